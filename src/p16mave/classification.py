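"""Replicate combination, FDR control and three-way functional classification.

Two classifiers are provided, mirroring the two analysis routes of the assay:

* ``gamma_glm`` — per-replicate upper-tail p-values from the calibrated null
  (see :mod:`p16mave.null_model`) are combined across replicates with
  Fisher's method; Benjamini-Hochberg controls the FDR over all tested
  variants; classes are assigned from log2 of the combined p-value.  In
  ``"published"`` mode the fixed published cutoffs are used (deleterious at
  log2 P <= -53.2, neutral at log2 P >= -5.8); in ``"adaptive"`` mode the
  data-dependent BH cutoff replaces the deleterious bound.

* ``fold_change`` — each variant's confluency/Day-9 proportion ratio is
  normalised to the synonymous variant at its residue (NFC); log2 NFC is
  averaged across replicates; cutoffs either fixed (neutral <= 0.24,
  deleterious >= 1.09) or derived from benchmark variant sets (deleterious
  bound = minimum benchmark-pathogenic log2 NFC, neutral bound = maximum
  benchmark-benign log2 NFC).

Only a fitness advantage is classified; depleted (putative gain-of-function)
variants are reported descriptively through their statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import null_model as nm

__all__ = [
    "ClassificationThresholds",
    "CLASSES",
    "combine_pvalues_fisher",
    "combine_log_pvalues",
    "bh_fdr",
    "BHResult",
    "classify_glm",
    "glm_classify_table",
    "foldchange_classify",
    "replicate_concordance",
    "ConcordanceSummary",
]

CLASSES = ("deleterious", "indeterminate", "neutral")
LN2 = math.log(2.0)


@dataclass(frozen=True)
class ClassificationThresholds:
    """Classification cutoffs.  log2 P bounds follow the published inequalities
    (<= deleterious, >= neutral); NFC bounds are on log2 normalized fold
    change (neutral <= 0.24, deleterious >= 1.09)."""

    fdr_level: float = 0.05
    log2p_deleterious: float = -53.2
    log2p_neutral: float = -5.8
    nfc_deleterious_min: float = 1.09
    nfc_neutral_max: float = 0.24

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must be in (0, 1)")
        if not self.log2p_deleterious < self.log2p_neutral <= 0.0:
            raise ValueError("require log2p_deleterious < log2p_neutral <= 0")
        if not self.nfc_neutral_max < self.nfc_deleterious_min:
            raise ValueError("require nfc_neutral_max < nfc_deleterious_min")


def _check_pvalues(p: np.ndarray) -> None:
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")


def combine_pvalues_fisher(p_values: Sequence[float]) -> float:
    """Fisher's method: upper tail of chi-square(2k) at -2 * sum(log p_i).

    A single p-value passes through unchanged (the k=1 identity)."""
    p = np.asarray(list(p_values), dtype=float)
    _check_pvalues(p)
    stat = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(stat, 2 * p.size))


def combine_log_pvalues(log_p_values: Sequence[float]) -> float:
    """Fisher's method on natural-log p-values, returning the natural log of
    the combined p-value (no underflow for extreme tails)."""
    lp = np.asarray(list(log_p_values), dtype=float)
    if lp.size == 0:
        raise ValueError("empty p-value list")
    if np.any(lp > 0):
        raise ValueError("log p-values must be <= 0")
    stat = -2.0 * lp.sum()
    return float(stats.chi2.logsf(stat, 2 * lp.size))


class BHResult(NamedTuple):
    reject: np.ndarray
    adjusted: np.ndarray
    cutoff: float  # largest raw p among rejections (NaN when none)


def bh_fdr(p_values: Sequence[float], fdr_level: float = 0.05) -> BHResult:
    """Benjamini-Hochberg step-up over the supplied p-values.

    Returns rejection flags, BH-adjusted p-values and the data-dependent raw-p
    significance cutoff (largest raw p among rejections), the quantity used by
    adaptive classification.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=fdr_level, method="fdr_bh")
    cutoff = float(p[reject].max()) if reject.any() else float("nan")
    return BHResult(reject, adjusted, cutoff)


def classify_glm(
    combined_p: float | None = None,
    thresholds: ClassificationThresholds | None = None,
    mode: str = "published",
    *,
    log2_p: float | None = None,
    bh_cutoff: float | None = None,
) -> str:
    """Three-way class from a combined p-value (or its log2, for tails that
    underflow).

    ``"published"`` mode applies the fixed log2 P cutoffs; ``"adaptive"`` mode
    calls a variant deleterious when its combined p-value is at or below the
    BH raw-p cutoff, neutral at/above the configured neutral bound, and
    indeterminate otherwise.  Boundary values follow the published
    inequalities (<= deleterious, >= neutral).
    """
    t = thresholds or ClassificationThresholds()
    if log2_p is None:
        if combined_p is None:
            raise ValueError("provide combined_p or log2_p")
        if not 0.0 < combined_p <= 1.0:
            raise ValueError("combined_p must lie in (0, 1]")
        log2_p = math.log2(combined_p)
    if mode == "published":
        if log2_p <= t.log2p_deleterious:
            return "deleterious"
        if log2_p >= t.log2p_neutral:
            return "neutral"
        return "indeterminate"
    if mode == "adaptive":
        if bh_cutoff is None or math.isnan(bh_cutoff):
            rejected = False
        else:
            p = combined_p if combined_p is not None else 2.0 ** log2_p
            rejected = p <= bh_cutoff
        if rejected:
            return "deleterious"
        if log2_p >= t.log2p_neutral:
            return "neutral"
        return "indeterminate"
    raise ValueError(f"unknown mode {mode!r}")


def glm_classify_table(
    count_table: pd.DataFrame,
    model: nm.NullModel,
    thresholds: ClassificationThresholds | None = None,
    mode: str = "published",
    pseudocount: float | None = 0.5,
) -> pd.DataFrame:
    """Full gamma-GLM classification of an assay count table.

    Builds synonymous-anchored triplets per replicate, evaluates per-replicate
    log p-values under ``model``, combines replicates with Fisher's method,
    applies BH across all tested variants, and assigns classes per ``mode``.
    Returns one row per variant with columns ``variant``, ``residue_index``,
    ``n_replicates``, per-replicate ``p_rep*``, ``p_combined``, ``log2_p``,
    ``p_adjusted``, ``reject_bh`` and ``class_glm``.
    """
    t = thresholds or ClassificationThresholds()
    trips = nm.assay_triplets(count_table, pseudocount=pseudocount)
    if trips.empty:
        raise ValueError("no triplets could be built from the count table")
    trips = trips.assign(log_p=nm.log_pvalues(trips, model))

    records = []
    for (variant, residue), group in trips.groupby(["variant", "residue_index"], sort=True):
        lps = group["log_p"].to_numpy()
        log_comb = combine_log_pvalues(lps) if len(lps) > 1 else float(lps[0])
        rec = {
            "variant": variant,
            "residue_index": int(residue),
            "n_replicates": len(lps),
            "p_combined": math.exp(log_comb),
            "log2_p": log_comb / LN2,
        }
        for i, lp in enumerate(lps, start=1):
            rec[f"p_rep{i}"] = math.exp(lp)
        records.append(rec)
    results = pd.DataFrame(records)

    bh = bh_fdr(results["p_combined"].to_numpy(), t.fdr_level)
    results["p_adjusted"] = bh.adjusted
    results["reject_bh"] = bh.reject
    results["class_glm"] = [
        classify_glm(log2_p=l2p, thresholds=t, mode=mode, bh_cutoff=bh.cutoff)
        for l2p in results["log2_p"]
    ]
    return results


def foldchange_classify(
    count_table: pd.DataFrame,
    thresholds: ClassificationThresholds | None = None,
    benchmark_pathogenic: Sequence[float] | None = None,
    benchmark_benign: Sequence[float] | None = None,
    pseudocount: float | None = 0.5,
) -> pd.DataFrame:
    """Normalized-fold-change classification.

    Per library and replicate: FC_v = (confluency proportion)/(Day-9
    proportion); NFC_v = FC_v / FC of the synonymous variant at that residue;
    log2 NFC is averaged across replicates per variant.  A variant is
    deleterious when mean log2 NFC >= ``nfc_deleterious_min`` and neutral when
    <= ``nfc_neutral_max``.  When benchmark log2 NFC sets are supplied the
    cutoffs are derived from them instead: deleterious bound = min of the
    pathogenic set, neutral bound = max of the benign set.
    """
    t = thresholds or ClassificationThresholds()
    del_min, neu_max = t.nfc_deleterious_min, t.nfc_neutral_max
    if benchmark_pathogenic is not None or benchmark_benign is not None:
        if not benchmark_pathogenic or not benchmark_benign:
            raise ValueError("both benchmark sets are required to derive thresholds")
        del_min = float(min(benchmark_pathogenic))
        neu_max = float(max(benchmark_benign))
        if neu_max >= del_min:
            raise ValueError("benchmark sets overlap: no indeterminate band exists")

    rows = []
    for (lib, rep), group in count_table.groupby(["library_id", "replicate_id"], sort=True):
        is_syn = (group["alt_aa"] == group["ref_aa"]).to_numpy()
        if is_syn.sum() != 1:
            raise ValueError(f"library {lib!r} replicate {rep!r}: missing synonymous anchor")
        c9 = group["count_day9"].to_numpy(dtype=float)
        ccf = group["count_confluent"].to_numpy(dtype=float)
        if pseudocount is not None:
            c9 = c9 + pseudocount
            ccf = ccf + pseudocount
        elif (c9 <= 0).any() or (ccf <= 0).any():
            raise ValueError("zero count with pseudocounting disabled")
        fc = (ccf / ccf.sum()) / (c9 / c9.sum())
        nfc = fc / fc[is_syn][0]
        res = int(group["residue_index"].iloc[0])
        ref_aa = group["ref_aa"].iloc[0]
        for alt, val in zip(group["alt_aa"], np.log2(nfc)):
            rows.append((f"{ref_aa}{res}{alt}", res, alt == ref_aa, val))
    per_rep = pd.DataFrame(rows, columns=["variant", "residue_index", "is_synonymous", "log2_nfc"])

    agg = (
        per_rep.groupby(["variant", "residue_index", "is_synonymous"], sort=True)["log2_nfc"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "log2_nfc", "size": "n_replicates"})
    )

    def _cls(x: float) -> str:
        if x >= del_min:
            return "deleterious"
        if x <= neu_max:
            return "neutral"
        return "indeterminate"

    agg["class_foldchange"] = agg["log2_nfc"].map(_cls)
    agg.attrs["nfc_deleterious_min"] = del_min
    agg.attrs["nfc_neutral_max"] = neu_max
    return agg


class ConcordanceSummary(NamedTuple):
    crosstab: pd.DataFrame
    percent_concordant: float
    n_flips: int  # deleterious <-> neutral disagreements


def replicate_concordance(
    results_rep1: Mapping[str, str] | pd.Series,
    results_rep2: Mapping[str, str] | pd.Series,
) -> ConcordanceSummary:
    """Cross-tabulate functional classes between two replicate analyses.

    Inputs map variant -> class; the variant sets must match exactly.  The
    flip count covers only deleterious-in-one / neutral-in-the-other
    disagreements; deleterious vs indeterminate is discordant but not a flip.
    """
    s1 = pd.Series(dict(results_rep1)) if not isinstance(results_rep1, pd.Series) else results_rep1
    s2 = pd.Series(dict(results_rep2)) if not isinstance(results_rep2, pd.Series) else results_rep2
    if set(s1.index) != set(s2.index):
        raise ValueError("replicates cover different variant sets")
    s2 = s2.reindex(s1.index)
    tab = pd.crosstab(
        pd.Categorical(s1, categories=CLASSES),
        pd.Categorical(s2, categories=CLASSES),
        dropna=False,
    )
    tab.index.name, tab.columns.name = "replicate_1", "replicate_2"
    n = len(s1)
    concordant = int((s1.to_numpy() == s2.to_numpy()).sum())
    flips = int(tab.loc["deleterious", "neutral"] + tab.loc["neutral", "deleterious"])
    return ConcordanceSummary(tab, 100.0 * concordant / n, flips)
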