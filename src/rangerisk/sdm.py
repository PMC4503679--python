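"""Presence/background species distribution models.

Three model families are supported, each a binary classifier of
presence records against random background points on the four climate
covariates:

``smooth_additive``
    a penalized additive logistic model (GAM): per-covariate B-spline
    smooths with a ridge penalty on the coefficients;
``recursive_partition``
    an axis-aligned classification tree (CART);
``kernel_classifier``
    an RBF support-vector machine with Platt-scaled probability
    outputs and a median-heuristic bandwidth.

Validation follows a median-latitude split (records exactly at the
median go to the northern half): the model is fitted on the northern
half and scored by ROC/AUC on the held-out southern presences against
held-out background of the chosen scheme (region-wide, or restricted to
the species' minimum convex polygon). The smooth-additive family is the
default used for projection downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .geometry import KM_PER_DEG, MCP
from .grids import CLIMATE_VARIABLES, ClimateStack, Grid

log = logging.getLogger(__name__)

METHODS = ("smooth_additive", "recursive_partition", "kernel_classifier")

#: fixed hyperparameters (the study protocol is silent on these)
GAM_KNOTS = 8  # knots per covariate smooth
GAM_C = 1.0  # inverse ridge strength of the additive logistic fit
TREE_MIN_LEAF = 7  # rpart's default minbucket (minsplit/3)
N_BACKGROUND = 1000


def resample_to_analysis_grid(stack: ClimateStack, target_cell_km2: float = 25.0) -> ClimateStack:
    """Aggregate a finer climate stack to the ~25 km^2 analysis lattice.

    Continuous layers are block-means; boolean/binary layers use the
    majority rule. Incomplete edge blocks are trimmed. Input already at
    or coarser than the target resolution is rejected.
    """
    target_deg = np.sqrt(target_cell_km2) / KM_PER_DEG
    ratio = target_deg / stack.cell_size_deg
    if ratio < 1.5:
        raise ValueError(
            "input must be finer than the analysis resolution "
            f"(cell {stack.cell_size_deg:.4g} deg vs target {target_deg:.4g} deg)"
        )
    factor = int(round(ratio))
    r, c = stack.shape
    r2, c2 = (r // factor) * factor, (c // factor) * factor
    out = {}
    for name, layer in stack:
        block = layer[:r2, :c2].reshape(r2 // factor, factor, c2 // factor, factor)
        vals = np.unique(layer[np.isfinite(layer)])
        if vals.size <= 2 and np.all(np.isin(vals, (0.0, 1.0))):
            out[name] = (block.mean(axis=(1, 3)) >= 0.5).astype(float)
        else:
            out[name] = block.mean(axis=(1, 3))
    return ClimateStack(out, stack.origin, stack.cell_size_deg * factor, stack.epoch)


def pca_screen(
    stack: ClimateStack, candidate_layers: tuple[str, ...] | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Collinearity screen: standardized PCA over cell values.

    Returns (loadings table: layers x components, explained variance
    ratios). Constant layers are dropped with a warning. The final
    predictor choice is configuration; the default set is the four
    canonical bioclimatic variables in CLIMATE_VARIABLES.
    """
    names = list(candidate_layers or stack.names)
    if len(names) < 2:
        raise ValueError("need at least two candidate layers")
    cols, kept = [], []
    for name in names:
        v = stack.layers[name].ravel()
        if np.nanstd(v) == 0:
            warnings.warn(f"dropping constant layer {name!r} from PCA screen")
            continue
        cols.append(v)
        kept.append(name)
    X = StandardScaler().fit_transform(np.column_stack(cols))
    pca = PCA(n_components=len(kept))
    pca.fit(X)
    loadings = pd.DataFrame(
        pca.components_.T,
        index=kept,
        columns=[f"PC{i + 1}" for i in range(len(kept))],
    )
    return loadings, pca.explained_variance_ratio_


@dataclass
class BackgroundSample:
    points: np.ndarray  # (n, 2) lon/lat
    scheme: str  # region_wide | within_mcp
    n: int

    def __post_init__(self) -> None:
        if self.points.shape != (self.n, 2):
            raise ValueError("points must be (n, 2)")


def sample_background(
    grid: Grid,
    n: int = N_BACKGROUND,
    seed: int = 0,
    scheme: str = "region_wide",
    mcp: MCP | None = None,
    land_mask: np.ndarray | None = None,
) -> BackgroundSample:
    """Random background (pseudo-absence) points.

    region_wide: ``n`` points uniform over (land) cells of the study
    window. within_mcp: uniform points inside the species' minimum
    convex polygon, by rejection sampling over its bounding box.
    """
    rng = np.random.default_rng(seed)
    cell = grid.cell_size_deg
    if scheme == "region_wide":
        ok = np.ones(grid.data.shape, dtype=bool) if land_mask is None else land_mask.astype(bool)
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            raise ValueError("no cells available for background sampling")
        flat = rng.choice(idx, size=n)
        row, col = np.unravel_index(flat, grid.data.shape)
        lon = grid.west + (col + rng.random(n)) * cell
        lat = grid.north - (row + rng.random(n)) * cell
        return BackgroundSample(np.column_stack([lon, lat]), scheme, n)
    if scheme == "within_mcp":
        if mcp is None:
            raise ValueError("within_mcp scheme needs the species MCP")
        poly = mcp.polygon
        if poly.area <= 0:
            raise ValueError("degenerate MCP: zero area")
        minx, miny, maxx, maxy = poly.bounds
        pts = np.empty((0, 2))
        while len(pts) < n:
            m = max(4 * (n - len(pts)), 64)
            cand = np.column_stack(
                [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
            )
            keep = shapely.intersects_xy(poly, cand[:, 0], cand[:, 1])
            pts = np.vstack([pts, cand[keep]])
        return BackgroundSample(pts[:n], scheme, n)
    raise ValueError(f"unknown background scheme {scheme!r}")


def _design(stack: ClimateStack, points: np.ndarray, variables) -> np.ndarray:
    X = stack.covariates_at(points[:, 0], points[:, 1], variables)
    if np.isnan(X).any():
        raise ValueError("points fall outside the climate stack extent")
    return X


@dataclass
class SuitabilityModel:
    """A fitted presence/background classifier on climate covariates."""

    method: str
    predictors: tuple[str, ...]
    _state: dict = field(repr=False, default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Suitability in [0, 1] for an (n, k) covariate matrix.

        Covariates are clipped to the range seen in training: projection
        is never extrapolated beyond the fitted support.
        """
        X = np.clip(np.asarray(X, dtype=float), self._state["lo"], self._state["hi"])
        if self.method == "smooth_additive":
            with np.errstate(over="ignore"):
                p = self._state["clf"].predict_proba(X)[:, 1]
        elif self.method == "recursive_partition":
            p = self._state["clf"].predict_proba(X)[:, 1]
        else:
            p = self._state["clf"].predict_proba(self._state["scaler"].transform(X))[:, 1]
        return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)

    def predict_grid(self, stack: ClimateStack) -> np.ndarray:
        X = np.column_stack([stack.layers[v].ravel() for v in self.predictors])
        return self.predict(X).reshape(stack.shape)


def fit(
    method: str,
    presences: np.ndarray,
    background: BackgroundSample | np.ndarray,
    stack: ClimateStack,
    seed: int = 0,
    variables: tuple[str, ...] = CLIMATE_VARIABLES,
) -> SuitabilityModel:
    """Fit one model family to presence vs background points.

    Requires >= 5 presences. A covariate that is constant over the
    combined design is reported by name and rejected.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    presences = np.asarray(presences, dtype=float)
    if len(presences) < 5:
        raise ValueError("at least 5 presence records are required for modelling")
    bg = background.points if isinstance(background, BackgroundSample) else np.asarray(background)
    Xp = _design(stack, presences, variables)
    Xb = _design(stack, bg, variables)
    X = np.vstack([Xp, Xb])
    y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xb))])
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = [v for v, s in zip(variables, sds) if s == 0]
        raise ValueError(f"degenerate design: constant covariate(s) {bad}")
    state: dict = {"lo": X.min(axis=0), "hi": X.max(axis=0)}
    if method == "smooth_additive":
        # penalized additive logistic model: per-covariate B-spline basis
        # with an L2 (ridge) penalty; the ridge keeps coefficients finite
        # when presences are perfectly separable from background
        clf = Pipeline(
            [
                ("spline", SplineTransformer(n_knots=GAM_KNOTS, degree=3)),
                ("logit", LogisticRegression(C=GAM_C, max_iter=2000)),
            ]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state["clf"] = clf.fit(X, y)
    elif method == "recursive_partition":
        clf = DecisionTreeClassifier(min_samples_leaf=TREE_MIN_LEAF, random_state=seed)
        state["clf"] = clf.fit(X, y)
    else:
        scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)
        rng = np.random.default_rng(seed)
        sub = Xs if len(Xs) <= 500 else Xs[rng.choice(len(Xs), 500, replace=False)]
        med = np.median(pdist(sub))
        gamma = 1.0 / (2.0 * med**2) if med > 0 else "scale"
        clf = SVC(kernel="rbf", gamma=gamma, probability=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xs, y)
        state["scaler"] = scaler
        state["clf"] = clf
    return SuitabilityModel(method, tuple(variables), state)


def roc_auc(scores_pos, scores_neg) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    AUC = (number of (pos, neg) pairs with pos > neg, ties counted
    half) / (n_pos * n_neg) — exact, including ties.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass
class ValidationResult:
    species_id: str
    method: str
    scheme: str
    auc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc must lie in [0, 1]")


def validate_split(
    species_id: str,
    presences: np.ndarray,
    background: BackgroundSample,
    stack: ClimateStack,
    method: str = "smooth_additive",
    seed: int = 0,
    min_half: int = 3,
) -> ValidationResult | None:
    """Median-latitude split validation.

    Presences and background are both split at the median presence
    latitude (points exactly at the median go north); the model is
    fitted on the northern half and the AUC of held-out southern
    presences vs southern background is returned. Returns None (logged)
    when either presence half has fewer than ``min_half`` records or a
    background half is empty.
    """
    presences = np.asarray(presences, dtype=float)
    if len(presences) < 2 * min_half:
        log.warning("%s: too few records for split validation", species_id)
        return None
    med = np.median(presences[:, 1])
    north = presences[:, 1] >= med
    train_p, test_p = presences[north], presences[~north]
    bg_north = background.points[:, 1] >= med
    train_b, test_b = background.points[bg_north], background.points[~bg_north]
    if len(train_p) < max(min_half, 5) or len(test_p) < min_half:
        log.warning("%s: a latitude half has < %d presences; validation skipped",
                    species_id, min_half)
        return None
    if len(train_b) == 0 or len(test_b) == 0:
        log.warning("%s: empty background half; validation skipped", species_id)
        return None
    model = fit(method, train_p, train_b, stack, seed=seed)
    variables = model.predictors
    s_pos = model.predict(_design(stack, test_p, variables))
    s_neg = model.predict(_design(stack, test_b, variables))
    return ValidationResult(species_id, method, background.scheme, roc_auc(s_pos, s_neg))


def binarize(
    suitability: np.ndarray,
    presence_scores: np.ndarray,
    sensitivity: float = 0.9,
) -> tuple[np.ndarray, float]:
    """Binary range map from a suitability surface.

    The cutoff is the largest suitability value such that at least
    ``sensitivity`` of the training presences score at or above it
    (i.e. the ceil(sensitivity * n)-th largest presence score); cells
    with suitability >= cutoff are presence. Lowering the sensitivity
    can only shrink the range. Returns (mask, cutoff).
    """
    scores = np.sort(np.asarray(presence_scores, dtype=float))[::-1]
    if scores.size == 0:
        raise ValueError("need at least one presence score")
    if not 0 < sensitivity <= 1:
        raise ValueError("sensitivity must be in (0, 1]")
    suitability = np.asarray(suitability, dtype=float)
    if np.ptp(suitability) == 0:
        raise ValueError("all-constant suitability surface cannot be thresholded")
    k = int(np.ceil(sensitivity * scores.size))
    cutoff = float(scores[k - 1])
    return suitability >= cutoff, cutoff
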