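"""File formats, configuration and end-to-end pipeline orchestration.

All tabular outputs are tab-delimited UTF-8 with a header row and ``.`` for
missing values; models and provenance are JSON.  Every pipeline run writes a
provenance record (config echo, seed, package version) and one structured log
line per stage.  No stage mutates its inputs on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import __version__
from . import classification as cls
from . import domain_analysis as dom
from . import null_model as nm
from . import synthetic_data as sd
from .synthetic_data import COUNT_COLUMNS

__all__ = [
    "ConfigError",
    "ValidationError",
    "load_count_table",
    "write_count_table",
    "validate_run_config",
    "simulate_and_classify",
    "run_pipeline",
]

log = logging.getLogger("p16mave")

_AA_OK = set(sd.AMINO_ACIDS) | {"*", "-"}


class ConfigError(ValueError):
    """Invalid run configuration."""


class ValidationError(ValueError):
    """Malformed tabular input; messages are row-addressed."""


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def load_count_table(path) -> pd.DataFrame:
    """Read and validate a canonical count table (TSV).

    Rejects missing columns, negative counts and malformed amino-acid codes
    with row-addressed messages, and duplicate (library, replicate, variant)
    rows.  An empty file yields an empty table with a logged warning.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", na_values=["."])
    except pd.errors.EmptyDataError:
        log.warning("count table %s is empty", path)
        return pd.DataFrame(columns=COUNT_COLUMNS)
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if table.empty:
        log.warning("count table %s has a header but no rows", path)
        return table
    for col in ("count_day9", "count_confluent"):
        bad = table.index[table[col].isna() | (table[col] < 0)]
        if len(bad):
            raise ValidationError(f"{path} row {bad[0] + 2}: negative or missing {col}")
    for col in ("ref_aa", "alt_aa"):
        vals = table[col].astype(str)
        bad = table.index[~(vals.isin(_AA_OK) | vals.str.fullmatch(r"TAG\d+").fillna(False))]
        if len(bad):
            raise ValidationError(
                f"{path} row {bad[0] + 2}: malformed amino-acid code {table[col].iloc[bad[0]]!r}"
            )
    key = ["library_id", "replicate_id", "residue_index", "alt_aa"]
    dup = table.duplicated(subset=key)
    if dup.any():
        row = int(table.index[dup][0])
        raise ValidationError(f"{path} row {row + 2}: duplicate (library, replicate, variant) entry")
    log.info("loaded %s: %d rows [sha256:%s]", path, len(table), _file_hash(path))
    return table


def write_count_table(table: pd.DataFrame, path) -> None:
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"count table to write is missing columns {missing}")
    table.to_csv(path, sep="\t", index=False, na_rep=".")


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=".")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "stages",
    "simulation",
    "thresholds",
    "classify_mode",
    "pseudocount",
    "control_tables",
    "count_tables",
    "n_control_experiments",
    "deleterious_fraction",
    "n_bootstrap",
}

_SIM_KEYS = {f.name for f in sd.SimulationConfig.__dataclass_fields__.values()}
_THRESH_KEYS = {f.name for f in cls.ClassificationThresholds.__dataclass_fields__.values()}


def validate_run_config(config: Mapping) -> dict:
    """Reject unknown keys and materialise nested dataclasses."""
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    out = dict(config)
    sim = dict(out.get("simulation", {}))
    bad = set(sim) - _SIM_KEYS
    if bad:
        raise ConfigError(f"unknown simulation keys: {sorted(bad)}")
    if "confluency_day_range" in sim:
        sim["confluency_day_range"] = tuple(sim["confluency_day_range"])
    out["simulation"] = sd.SimulationConfig(**sim)
    thr = dict(out.get("thresholds", {}))
    bad = set(thr) - _THRESH_KEYS
    if bad:
        raise ConfigError(f"unknown threshold keys: {sorted(bad)}")
    out["thresholds"] = cls.ClassificationThresholds(**thr)
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate_and_classify(
    config: sd.SimulationConfig,
    seed: int,
    mode: str = "adaptive",
    deleterious_fraction: float | None = None,
    thresholds: cls.ClassificationThresholds | None = None,
    n_control_experiments: int = 3,
):
    """One full in-silico pass: control + screen simulation, null calibration,
    p-values, Fisher combination, BH and classes.

    Returns ``(results, counts, model)`` where ``results`` carries the merged
    ground-truth labels (column ``is_deleterious``) for power/FDR accounting.
    The supplied ``seed`` drives both the control and screen substreams.
    """
    import numpy as np

    ss = np.random.SeedSequence(seed)
    control_seed, screen_seed = ss.spawn(2)
    controls = sd.simulate_celltag_control(config, control_seed, n_experiments=n_control_experiments)
    model = nm.fit_null(nm.build_triplets(controls))
    counts, truth = sd.simulate_screen(config, screen_seed, deleterious_fraction)
    results = cls.glm_classify_table(counts, model, thresholds, mode=mode)
    results = results.merge(truth, on="variant", how="left")
    return results, counts, model


def run_pipeline(config: Mapping, out_dir=None) -> dict:
    """Execute the requested stages and write all outputs plus provenance.

    Stages (``config["stages"]``, default all): ``simulate``, ``calibrate``,
    ``classify``, ``foldchange``, ``enrich``.  Identical config + seed give
    byte-identical outputs.  Returns a bundle of the in-memory results.
    """
    import numpy as np

    cfg = validate_run_config(config)
    sim_cfg: sd.SimulationConfig = cfg["simulation"]
    thresholds: cls.ClassificationThresholds = cfg["thresholds"]
    seed = int(cfg.get("seed", sim_cfg.seed))
    out = Path(out_dir or cfg.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    stages = list(cfg.get("stages", ["simulate", "calibrate", "classify", "foldchange", "enrich"]))
    pseudocount = cfg.get("pseudocount", 0.5)
    bundle: dict = {"seed": seed}

    ss = np.random.SeedSequence(seed)
    control_seed, screen_seed = ss.spawn(2)

    if "simulate" in stages:
        log.info("stage=simulate seed=%d residues=%d", seed, sim_cfg.n_residues)
        controls = sd.simulate_celltag_control(
            sim_cfg, control_seed, n_experiments=int(cfg.get("n_control_experiments", 3))
        )
        counts, truth = sd.simulate_screen(sim_cfg, screen_seed, cfg.get("deleterious_fraction"))
        for i, tab in enumerate(controls, start=1):
            write_count_table(tab, out / f"control_exp{i}.tsv")
        write_count_table(counts, out / "counts.tsv")
        write_table(truth, out / "truth.tsv")
        bundle.update(controls=controls, counts=counts, truth=truth)
    else:
        control_paths = cfg.get("control_tables") or []
        count_paths = cfg.get("count_tables") or []
        if "calibrate" in stages and not control_paths:
            raise ConfigError("calibrate stage requires control_tables when simulate is not run")
        if ("classify" in stages or "foldchange" in stages) and not count_paths:
            raise ConfigError("classify/foldchange stages require count_tables")
        bundle["controls"] = [load_count_table(p) for p in control_paths]
        if count_paths:
            bundle["counts"] = pd.concat([load_count_table(p) for p in count_paths], ignore_index=True)

    if "calibrate" in stages:
        triplets = nm.build_triplets(bundle["controls"], pseudocount=pseudocount)
        model = nm.fit_null(triplets)
        log.info("stage=calibrate n_triplets=%d alpha=%.3g a=%.3g b=%.3g",
                 len(triplets), model.shape, model.exp_rinit, model.exp_pinit)
        model.to_json(out / "null_model.json")
        write_table(triplets, out / "triplets.tsv")
        bundle.update(model=model, triplets=triplets)

    if "classify" in stages:
        results = cls.glm_classify_table(
            bundle["counts"], bundle["model"], thresholds,
            mode=cfg.get("classify_mode", "published"), pseudocount=pseudocount,
        )
        log.info("stage=classify variants=%d deleterious=%d", len(results),
                 int((results["class_glm"] == "deleterious").sum()))
        bundle["results"] = results

    if "foldchange" in stages:
        fc = cls.foldchange_classify(bundle["counts"], thresholds, pseudocount=pseudocount)
        log.info("stage=foldchange variants=%d", len(fc))
        bundle["foldchange"] = fc
        if "results" in bundle:
            bundle["results"] = bundle["results"].merge(
                fc[["variant", "log2_nfc", "class_foldchange"]], on="variant", how="left"
            )
        else:
            write_table(fc, out / "foldchange.tsv")

    if "results" in bundle:
        write_table(bundle["results"], out / "results.tsv")

    if "enrich" in stages and "results" in bundle:
        # Restrict the domain map to regions the screen actually covers
        # (partial screens legitimately omit repeats).
        residues = set(bundle["results"]["residue_index"])
        regions = {
            name: span
            for name, span in dom.ANKYRIN_REPEATS.items()
            if any(span[0] <= r <= span[1] for r in residues)
        }
        dm = dom.DomainMap(regions=regions)
        covered = {dom.assign_domain(int(r), dm) for r in residues}
        if len(covered) < 2:
            log.warning("stage=enrich skipped: screen covers a single region only")
            dm = None
        if dm is not None:
            enr = dom.domain_enrichment(bundle["results"], dm)
            write_table(enr, out / "domain_enrichment.tsv")
            bundle["enrichment"] = enr
        summ = dom.residue_summary(bundle["results"], n_bootstrap=int(cfg.get("n_bootstrap", 10_000)), seed=seed)
        log.info("stage=enrich mean_deleterious_fraction=%.4f", summ.mean_fraction)
        write_table(
            summ.per_residue.rename("deleterious_fraction").reset_index(), out / "residue_summary.tsv"
        )
        bundle["residue_summary"] = summ

    provenance = {
        "package": "p16mave",
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "thresholds": asdict(thresholds),
        "simulation": asdict(sim_cfg),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    return bundle
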