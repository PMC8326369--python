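"""End-to-end pipeline: filter -> accumulate -> fit -> classify -> match -> indval -> predict.

Every stage writes plain-text outputs into a run directory and is recorded in
a manifest (inputs' checksums, config, seed, versions). All randomness flows
from the single config seed through per-stage seeds derived from the stage
name, so toggling one stage never perturbs another, and a rerun with the same
config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .community_predict import (
    axis1_agreement,
    bray_curtis,
    nmds,
    predict_community,
    select_dominant_matched,
)
from .coverage_curves import per_habitat_curves
from .hof_fit import MODEL_TYPES, HOFFit, bootstrap_select
from .indicator_analysis import (
    assign_ph_groups,
    crosstab_indicators_vs_reference,
    significant_indicators,
)
from .otu_table import (
    filter_otus_by_prevalence,
    filter_samples,
    read_otu_table,
    relative_abundance,
    write_otu_table,
)
from .response_classify import ResponseClassification, classify_fit
from .sequence_match import (
    apply_hit_criteria,
    percent_hits,
    rank_bin_match_rates,
    read_match_table,
)

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "run_pipeline",
    "stage_seed",
    "fit_table",
    "fits_to_frame",
    "fits_from_frame",
]

logger = logging.getLogger(__name__)

STAGES = ("filter", "accumulate", "fit", "classify", "match", "indval", "predict")


@dataclass
class PipelineConfig:
    """Paths and the fixed analysis constants of the whole pipeline."""

    counts: str
    metadata: str
    matches: str
    query_counts: str
    query_metadata: str
    min_reads: int = 5000
    min_prevalence: int = 30
    t_low: float = 5.2
    t_high: float = 7.0
    min_identity: float = 97.0
    max_evalue: float = 0.001
    n_boot: int = 100
    n_perm: int = 999
    n_bins: int = 1000
    top_n: int = 100
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_reads < 0 or self.min_prevalence < 0:
            raise ValueError("filter thresholds must be non-negative")
        if not self.t_low < self.t_high:
            raise ValueError("t_low must be below t_high")
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity must be in [0, 100]")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Plain-text key=value config; explicit keyword overrides win."""
        kv: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key=value")
            key, val = line.split("=", 1)
            kv[key.strip()] = val.strip()
        kv.update({k: v for k, v in overrides.items() if v is not None})
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        typed: dict[str, object] = {}
        for key, val in kv.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            ftype = fields[key]
            if "int" in str(ftype):
                typed[key] = int(val)
            elif "float" in str(ftype):
                typed[key] = float(val)
            else:
                typed[key] = str(val)
        return cls(**typed)


class PipelineStageError(RuntimeError):
    """A stage failed; partial outputs of earlier stages are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed + stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ----------------------------------------------------------------------------
# fit serialization
# ----------------------------------------------------------------------------

def fit_table(table, n_boot: int = 100, seed: int | None = None,
              gradient_range: tuple[float, float] | None = None) -> dict[str, HOFFit]:
    """Bootstrap-selected HOF fit per OTU of a filtered table."""
    ph = table.ph.to_numpy()
    if gradient_range is None:
        gradient_range = (float(ph.min()), float(ph.max()))
    ss = np.random.SeedSequence(seed)
    fits: dict[str, HOFFit] = {}
    for child, otu in zip(ss.spawn(table.n_otus), table.otu_ids):
        counts = table.counts.loc[otu].to_numpy()
        fits[otu] = bootstrap_select(
            counts, ph, n_boot=n_boot,
            seed=np.random.default_rng(child),
            gradient_range=gradient_range, otu_id=otu,
        )
    return fits


def fits_to_frame(fits: Mapping[str, HOFFit]) -> pd.DataFrame:
    rows = []
    for otu, f in fits.items():
        p = list(f.params) + [np.nan] * (4 - len(f.params))
        opt = list(f.optima_pH) + [np.nan] * (2 - len(f.optima_pH))
        row = {
            "otu_id": otu, "model_type": f.model_type,
            "a": p[0], "b": p[1], "c": p[2], "d": p[3],
            "M": f.M, "logLik": f.logLik, "AIC": f.AIC,
            "opt1_pH": opt[0], "opt2_pH": opt[1],
        }
        for t in MODEL_TYPES:
            row[f"boot_{t}"] = f.bootstrap_tally.get(t, 0)
        row["n_boot_failed"] = f.n_boot_failed
        row["reversed"] = int(f.reversed_gradient)
        row["ph_min"], row["ph_max"] = f.gradient_range
        rows.append(row)
    return pd.DataFrame(rows)


def fits_from_frame(df: pd.DataFrame) -> dict[str, HOFFit]:
    from .hof_fit import N_FREE_PARAMS

    fits = {}
    for _, r in df.iterrows():
        k = N_FREE_PARAMS[r["model_type"]]
        params = tuple(float(r[c]) for c in ("a", "b", "c", "d")[:k])
        optima = tuple(float(r[c]) for c in ("opt1_pH", "opt2_pH") if pd.notna(r[c]))
        fits[str(r["otu_id"])] = HOFFit(
            otu_id=str(r["otu_id"]), model_type=str(r["model_type"]), params=params,
            M=float(r["M"]), logLik=float(r["logLik"]), k=k, AIC=float(r["AIC"]),
            reversed_gradient=bool(r["reversed"]),
            gradient_range=(float(r["ph_min"]), float(r["ph_max"])),
            optima_pH=optima,
            bootstrap_tally={t: int(r[f"boot_{t}"]) for t in MODEL_TYPES},
            n_boot_failed=int(r["n_boot_failed"]),
        )
    return fits


def classifications_from_fits(fits: Mapping[str, HOFFit], t_low: float, t_high: float) -> dict[str, ResponseClassification]:
    return {otu: classify_fit(f, t_low, t_high) for otu, f in fits.items()}


# ----------------------------------------------------------------------------
# the pipeline
# ----------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages in order; returns the manifest dictionary.

    Outputs land in ``outdir``; a ``manifest.json`` records per-stage output
    checksums, the config, the master seed and package versions. A stage
    failure raises :class:`PipelineStageError` naming the stage, with earlier
    stages' outputs preserved on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": {"ecohof": __version__},
        "inputs": {},
        "stages": {},
    }
    for key in ("counts", "metadata", "matches", "query_counts", "query_metadata"):
        manifest["inputs"][key] = _sha256(Path(getattr(config, key)))

    state: dict = {}

    def record(stage: str, outputs: dict[str, Path], extra: dict | None = None) -> None:
        manifest["stages"][stage] = {
            "outputs": {name: _sha256(p) for name, p in outputs.items()},
            **(extra or {}),
        }

    def run_stage(stage: str, fn) -> None:
        logger.info("stage %s", stage)
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - wrap with stage context
            raise PipelineStageError(stage, exc) from exc

    # -- filter ---------------------------------------------------------------
    def _filter() -> None:
        table = read_otu_table(config.counts, config.metadata)
        table = filter_samples(table, config.min_reads)
        if table.n_samples == 0:
            raise ValueError("0 samples after filtering")
        table = filter_otus_by_prevalence(table, config.min_prevalence)
        state["reference"] = table
        c, m = outdir / "filtered_counts.tsv", outdir / "filtered_metadata.csv"
        write_otu_table(table, c, m)
        record("filter", {"counts": c, "metadata": m},
               {"n_otus": table.n_otus, "n_samples": table.n_samples})

    # -- accumulate -----------------------------------------------------------
    def _accumulate() -> None:
        curves = per_habitat_curves(
            state["reference"], n_perm=100, seed=stage_seed(config.seed, "accumulate"))
        df = pd.concat([c.to_frame() for c in curves], ignore_index=True)
        p = outdir / "accumulation_curves.csv"
        df.to_csv(p, index=False)
        record("accumulate", {"curves": p})

    # -- fit ------------------------------------------------------------------
    def _fit() -> None:
        fits = fit_table(
            state["reference"], n_boot=config.n_boot,
            seed=stage_seed(config.seed, "fit"))
        state["fits"] = fits
        p = outdir / "fits.csv"
        fits_to_frame(fits).to_csv(p, index=False)
        record("fit", {"fits": p})

    # -- classify -------------------------------------------------------------
    def _classify() -> None:
        classes = classifications_from_fits(state["fits"], config.t_low, config.t_high)
        state["classes"] = classes
        rows = []
        for otu, c in classes.items():
            f = state["fits"][otu]
            opt = list(c.optima_pH) + [np.nan] * (2 - len(c.optima_pH))
            rows.append({"otu_id": otu, "model_type": f.model_type,
                         "opt1_pH": opt[0], "opt2_pH": opt[1],
                         "pH_class": c.response_class})
        p = outdir / "classes.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        record("classify", {"classes": p})

    # -- match ----------------------------------------------------------------
    def _match() -> None:
        hits = read_match_table(config.matches)
        best = apply_hit_criteria(hits, config.min_identity, config.max_evalue)
        state["best_hits"] = best
        query = read_otu_table(config.query_counts, config.query_metadata)
        state["query"] = query
        pct = percent_hits(query.otu_ids, best)
        n_bins = min(config.n_bins, query.n_otus)
        bins = rank_bin_match_rates(query.counts.sum(axis=1), best, n_bins=n_bins)
        p1 = outdir / "coverage.csv"
        bins.to_csv(p1, index=False)
        p2 = outdir / "best_hits.csv"
        pd.DataFrame(
            [{"query_id": q, "subject_id": h.subject_id,
              "pct_identity": h.pct_identity, "evalue": h.evalue,
              "bitscore": h.bitscore} for q, h in sorted(best.items())]
        ).to_csv(p2, index=False)
        record("match", {"coverage": p1, "best_hits": p2},
               {"percent_hits": pct, "n_bins": n_bins})

    # -- indval ---------------------------------------------------------------
    def _indval() -> None:
        query = state["query"]
        groups = assign_ph_groups(query.metadata, config.t_low, config.t_high)
        indicators = significant_indicators(
            query, groups, n_perm=config.n_perm, alpha=config.alpha,
            seed=stage_seed(config.seed, "indval"))
        cross = crosstab_indicators_vs_reference(
            indicators, state["best_hits"], state["classes"])
        p = outdir / "indicators.csv"
        indicators.join(cross["table"].drop(columns=["observed_band"])).to_csv(p)
        record("indval", {"indicators": p},
               {"n_indicators": len(indicators), "agreement": cross["agreement"],
                "n_matched": cross["n_matched"], "n_unmatched": cross["n_unmatched"]})

    # -- predict --------------------------------------------------------------
    def _predict() -> None:
        query = state["query"]
        dominant = select_dominant_matched(query, state["best_hits"], config.top_n)
        ref_median_depth = float(state["reference"].depths.median())
        pred = predict_community(
            state["fits"], dominant, query.metadata, ref_median_depth)
        seed = stage_seed(config.seed, "predict")
        pred_rel = pred.predicted / pred.predicted.sum(axis=0).replace(0, np.nan)
        pred_rel = pred_rel.fillna(0.0)
        nm_pred = nmds(bray_curtis(pred_rel), n_restarts=4, seed=seed)
        obs_rel = relative_abundance(query)
        nm_obs = nmds(bray_curtis(obs_rel), n_restarts=4, seed=seed + 1)
        r2 = axis1_agreement(nm_pred.scores, nm_obs.scores)
        p1 = outdir / "predicted.csv"
        pred.predicted.to_csv(p1)
        p2 = outdir / "scores.csv"
        pd.DataFrame(
            {"sample_id": query.sample_ids,
             "predicted_axis1": nm_pred.scores[:, 0],
             "observed_axis1": nm_obs.scores[:, 0]}
        ).to_csv(p2, index=False)
        record("predict", {"predicted": p1, "scores": p2},
               {"axis1_r2": r2, "stress_predicted": nm_pred.stress,
                "stress_observed": nm_obs.stress, "n_dominant": len(dominant)})

    for stage, fn in zip(
        STAGES, (_filter, _accumulate, _fit, _classify, _match, _indval, _predict)
    ):
        run_stage(stage, fn)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
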