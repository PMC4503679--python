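"""IUCN Red List classification, transition accounting and the Red List
Index.

Two criteria are applied in threshold-only form:

* criterion B1 — extent of occurrence (EOO) size: CR < 100 km^2,
  EN < 5,000 km^2, VU < 20,000 km^2, else LC;
* criterion A3 — projected future population reduction, proxied by the
  projected proportional EOO decline: CR >= 80%, EN >= 50%, VU >= 30%,
  else LC. Abundance is assumed linear in EOO, and a projected
  *expansion* counts as zero decline for classification.

The Red List Index is RLI = (M - T) / M with category weights LC=0,
NT=1, VU=2, EN=3, CR=4 and W_EX=5; M = W_EX times the number of
species, T the weight-weighted category sum. RLI is 1 when every
species is Least Concern and 0 when all are Extinct.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class Category(str, Enum):
    EX = "EX"
    CR = "CR"
    EN = "EN"
    VU = "VU"
    NT = "NT"
    LC = "LC"
    DD = "DD"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: category weights; also the severity order (larger = more severe).
WEIGHTS: dict[Category, int] = {
    Category.LC: 0,
    Category.NT: 1,
    Category.VU: 2,
    Category.EN: 3,
    Category.CR: 4,
    Category.EX: 5,
}
W_EX = WEIGHTS[Category.EX]

#: display order for tables, most to least severe, DD last
CATEGORY_ORDER = (Category.CR, Category.EN, Category.VU, Category.NT, Category.LC, Category.DD)

THREATENED = (Category.CR, Category.EN, Category.VU)

B1_THRESHOLDS_KM2 = (100.0, 5000.0, 20000.0)
A3_THRESHOLDS = (0.30, 0.50, 0.80)


def _as_category(c) -> Category:
    return c if isinstance(c, Category) else Category(str(c))


def severity(c) -> int:
    """Rank on the severity order; DD has no rank (raises)."""
    c = _as_category(c)
    if c is Category.DD:
        raise ValueError("DD is outside the severity order")
    return WEIGHTS[c]


def classify_B1(eoo_km2: float, thresholds: tuple[float, float, float] = B1_THRESHOLDS_KM2) -> Category:
    """Threshold-only criterion B1 from an EOO in km^2."""
    if eoo_km2 < 0:
        raise ValueError("eoo_km2 must be >= 0")
    cr, en, vu = thresholds
    if eoo_km2 < cr:
        return Category.CR
    if eoo_km2 < en:
        return Category.EN
    if eoo_km2 < vu:
        return Category.VU
    return Category.LC


def classify_A3(decline_fraction: float | None, thresholds: tuple[float, float, float] = A3_THRESHOLDS) -> Category:
    """Criterion A3 from a projected proportional decline.

    An undefined decline (None/NaN — zero current EOO) gives DD; a
    negative decline (projected expansion) is treated as zero.
    """
    if decline_fraction is None or (isinstance(decline_fraction, float) and np.isnan(decline_fraction)):
        return Category.DD
    d = max(float(decline_fraction), 0.0)
    vu, en, cr = thresholds
    if d >= cr:
        return Category.CR
    if d >= en:
        return Category.EN
    if d >= vu:
        return Category.VU
    return Category.LC


def combine_highest(a, b) -> Category:
    """The more severe of two categories (a lattice join on the severity
    order, with DD as the identity element)."""
    a, b = _as_category(a), _as_category(b)
    if a is Category.DD:
        return b
    if b is Category.DD:
        return a
    return a if severity(a) >= severity(b) else b


@dataclass
class Assessment:
    species_id: str
    category: Category
    basis: str  # formal | B1_present | B1_modelled | A3_<scenario> | combined_highest
    decline_fraction: float | None = None
    note: str = ""


def transition_matrix(
    base: Mapping[str, Category], alt: Mapping[str, Category], margins: bool = True
) -> pd.DataFrame:
    """Cross-tabulate categories: columns = base assessment, rows = the
    alternative (e.g. climate-change A3) assessment.

    Both mappings must cover exactly the same species.
    """
    if set(base) != set(alt):
        missing = set(base) ^ set(alt)
        raise ValueError(f"species sets differ between assessments: {sorted(missing)[:5]} ...")
    labels = [c.value for c in CATEGORY_ORDER]
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for sid in base:
        mat.loc[_as_category(alt[sid]).value, _as_category(base[sid]).value] += 1
    if margins:
        mat["Total"] = mat.sum(axis=1)
        mat.loc["Total"] = mat.sum(axis=0)
    return mat


def _core(matrix: pd.DataFrame) -> pd.DataFrame:
    labels = [c.value for c in CATEGORY_ORDER]
    return matrix.loc[[l for l in labels if l in matrix.index],
                      [l for l in labels if l in matrix.columns]]


def count_uplisted(matrix: pd.DataFrame) -> int:
    """Species whose row (new) category is strictly more severe than
    their column (old) category; DD rows/columns are excluded."""
    core = _core(matrix)
    total = 0
    for new in core.index:
        for old in core.columns:
            if new == "DD" or old == "DD":
                continue
            if severity(new) > severity(old):
                total += int(core.loc[new, old])
    return total


def threatened_total(counts: Mapping) -> int:
    """Number of species in a threatened category (CR + EN + VU)."""
    return sum(int(counts.get(c, counts.get(c.value, 0))) for c in THREATENED)


def category_counts(categories: Iterable) -> dict[Category, int]:
    out = {c: 0 for c in CATEGORY_ORDER}
    for c in categories:
        out[_as_category(c)] += 1
    return out


def rli(counts: Mapping, dd_policy: str = "weight_zero") -> float:
    """Red List Index from category counts.

    dd_policy:
      * ``weight_zero`` (default): DD species stay in the species count
        N and contribute weight 0 to T;
      * ``exclude``: DD species are dropped from N entirely.
    """
    report = rli_report(counts, dd_policy)
    return report["rli"]


def rli_report(counts: Mapping, dd_policy: str = "weight_zero") -> dict:
    """RLI with its bookkeeping (N, T, M) exposed."""
    if dd_policy not in ("weight_zero", "exclude"):
        raise ValueError(f"unknown dd_policy {dd_policy!r}")
    clean: dict[Category, int] = {}
    for key, n in counts.items():
        c = _as_category(key)
        n = int(n)
        if n < 0:
            raise ValueError("category counts must be >= 0")
        clean[c] = clean.get(c, 0) + n
    n_dd = clean.get(Category.DD, 0)
    n_total = sum(clean.values())
    if dd_policy == "exclude":
        n_total -= n_dd
    if n_total <= 0:
        raise ValueError("RLI needs at least one species")
    T = sum(WEIGHTS[c] * n for c, n in clean.items() if c is not Category.DD)
    M = W_EX * n_total
    return {
        "dd_policy": dd_policy,
        "counts": {c.value: n for c, n in clean.items()},
        "n_species": n_total,
        "T": T,
        "M": M,
        "rli": (M - T) / M,
    }


def assessments_to_frame(assessments: Iterable[Assessment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": a.species_id,
                "basis": a.basis,
                "category": a.category.value,
                "decline_fraction": a.decline_fraction,
                "note": a.note,
            }
            for a in assessments
        ]
    )
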