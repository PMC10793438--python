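"""Protein-domain summaries and enrichment of deleterious variants.

p16INK4a consists of four ~30-residue ankyrin repeats (protein-protein
interaction motifs) at codons 11-40, 44-72, 77-106 and 110-139; everything
else within the 156-residue protein is "non-ANK".  This module assigns
residues to these regions, tests each region's deleterious fraction against
its complement with a two-proportion z-test (Bonferroni-corrected across the
regions tested), and summarises per-residue deleterious fractions with a
bootstrap confidence interval for the protein-wide mean.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "DomainMap",
    "ANKYRIN_REPEATS",
    "ANKYRIN_SUBREGIONS",
    "parse_variant",
    "assign_domain",
    "domain_enrichment",
    "residue_summary",
    "ResidueSummary",
]

#: Ankyrin repeat intervals (1-based, inclusive).
ANKYRIN_REPEATS = {
    "ANK1": (11, 40),
    "ANK2": (44, 72),
    "ANK3": (77, 106),
    "ANK4": (110, 139),
}

#: 10-residue subregions of repeats 1-3 with concentrated deleterious variants.
ANKYRIN_SUBREGIONS = {
    "ANK1_core": (16, 25),
    "ANK2_core": (46, 55),
    "ANK3_core": (80, 89),
}

_VARIANT_RE = re.compile(r"^([A-Y\-])(\d+)([A-Y\*])$")


def parse_variant(variant: str) -> tuple[str, int, str]:
    """``"G101W"`` -> ``("G", 101, "W")``."""
    m = _VARIANT_RE.match(variant)
    if not m:
        raise ValueError(f"malformed variant name {variant!r}")
    return m.group(1), int(m.group(2)), m.group(3)


@dataclass(frozen=True)
class DomainMap:
    """Named inclusive residue intervals over a protein of ``protein_length``
    residues; residues in no named interval map to ``complement_name``."""

    regions: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(ANKYRIN_REPEATS)
    )
    protein_length: int = 156
    complement_name: str = "non-ANK"

    def __post_init__(self) -> None:
        spans = sorted(self.regions.items(), key=lambda kv: kv[1])
        prev_end = 0
        for name, (start, end) in spans:
            if not (1 <= start <= end <= self.protein_length):
                raise ValueError(f"region {name} {start}-{end} outside protein bounds")
            if start <= prev_end:
                raise ValueError(f"region {name} overlaps a previous region")
            prev_end = end

    @property
    def region_names(self) -> list[str]:
        return list(self.regions) + [self.complement_name]

    def region_size(self, name: str) -> int:
        if name == self.complement_name:
            return self.protein_length - sum(e - s + 1 for s, e in self.regions.values())
        start, end = self.regions[name]
        return end - start + 1


def assign_domain(variant: str | int, domain_map: DomainMap | None = None) -> str:
    """Region name for a variant (``"G101W"``) or a bare residue index."""
    dm = domain_map or DomainMap()
    residue = variant if isinstance(variant, (int, np.integer)) else parse_variant(variant)[1]
    if not 1 <= residue <= dm.protein_length:
        raise ValueError(f"residue {residue} outside 1..{dm.protein_length}")
    for name, (start, end) in dm.regions.items():
        if start <= residue <= end:
            return name
    return dm.complement_name


def domain_enrichment(
    classes: pd.DataFrame,
    domain_map: DomainMap | None = None,
) -> pd.DataFrame:
    """Per-region enrichment/depletion of deleterious variants.

    ``classes`` needs a ``residue_index`` column and a class column (first of
    ``class_glm``/``class_foldchange``/``class`` found).  Each region's
    deleterious fraction is compared against the complement of that region
    with a two-sided two-proportion z-test (pooled variance); p-values are
    Bonferroni-corrected by the number of regions tested.  Raises on a region
    with no classified variants.
    """
    dm = domain_map or DomainMap()
    col = next((c for c in ("class_glm", "class_foldchange", "class") if c in classes), None)
    if col is None:
        raise ValueError("no class column found")
    region = classes["residue_index"].map(lambda r: assign_domain(int(r), dm))
    deleterious = (classes[col] == "deleterious").to_numpy()

    names = dm.region_names
    rows = []
    for name in names:
        inside = (region == name).to_numpy()
        n_in, n_out = int(inside.sum()), int((~inside).sum())
        if n_in == 0:
            raise ValueError(f"region {name} contains no classified variants")
        x_in = int(deleterious[inside].sum())
        x_out = int(deleterious[~inside].sum())
        if n_out == 0:
            raise ValueError("domain map leaves no complement to compare against")
        if x_in + x_out == 0 or x_in + x_out == n_in + n_out:
            z, p = 0.0, 1.0  # no variation in either direction
        else:
            z, p = proportions_ztest([x_in, x_out], [n_in, n_out], alternative="two-sided")
        rows.append(
            {
                "region": name,
                "n": n_in,
                "n_deleterious": x_in,
                "proportion": x_in / n_in,
                "z": float(z),
                "p": float(p),
                "p_adj": min(1.0, float(p) * len(names)),
            }
        )
    return pd.DataFrame(rows)


class ResidueSummary(NamedTuple):
    per_residue: pd.Series  # residue -> deleterious fraction among missense
    mean_fraction: float
    ci_low: float
    ci_high: float


def residue_summary(
    classes: pd.DataFrame,
    n_bootstrap: int = 10_000,
    seed: int = 0,
) -> ResidueSummary:
    """Per-residue deleterious fraction and the protein-wide mean with a
    percentile-bootstrap 95% CI over residues.

    Only missense variants enter the fractions (the synonymous anchor, where
    present, is excluded by its variant name).  The bootstrap resamples
    residues with replacement, ``n_bootstrap`` times, seeded.
    """
    if classes.empty:
        raise ValueError("no classified variants")
    col = next((c for c in ("class_glm", "class_foldchange", "class") if c in classes), None)
    if col is None:
        raise ValueError("no class column found")
    refs, alts = zip(*[(parse_variant(v)[0], parse_variant(v)[2]) for v in classes["variant"]])
    missense = classes[[r != a for r, a in zip(refs, alts)]]
    frac = (
        missense.assign(is_del=missense[col] == "deleterious")
        .groupby("residue_index")["is_del"]
        .mean()
        .sort_index()
    )
    values = frac.to_numpy()
    mean = float(values.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_bootstrap, len(values)))
    boot_means = values[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return ResidueSummary(frac, mean, float(lo), float(hi))
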