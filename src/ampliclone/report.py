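"""End-to-end pipeline orchestration and distribution reports."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import build_association
from .background import BackgroundModel, estimate_background
from .calling import CohortCallSummary, call_cohort
from .enrichment import fit_enrichment, fit_enrichment_segments, series_from_table
from .errors import AmplicloneError, EmptyReportError, PipelineError
from .tables import CohortTable, read_count_table

__all__ = ["PipelineConfig", "run_pipeline", "render_distribution_report"]

log = logging.getLogger("ampliclone")


@dataclass(frozen=True)
class PipelineConfig:
    reference_path: str
    cohort_path: str
    out_dir: str
    k_sigma: float = 6.0
    n_trim: int = 2
    pseudocount: float = 0.5
    min_depth: int = 500
    passages: tuple[int, ...] = (0, 4, 9)
    association_passage: int | None = None  # default: last passage
    association_groups: tuple[str, str] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "passages" in raw:
            raw["passages"] = tuple(int(p) for p in raw["passages"])
        if raw.get("association_groups") is not None:
            raw["association_groups"] = tuple(raw["association_groups"])
        return cls(**raw)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _calls_frame(summaries: dict[int, CohortCallSummary]) -> pd.DataFrame:
    rows = []
    for passage, summary in summaries.items():
        for c in summary.calls:
            rows.append(
                {
                    "sample_id": c.sample_id,
                    "passage": passage,
                    "allele_fraction": c.allele_fraction,
                    "qc_pass": c.qc_pass,
                    "qc_reason": c.qc_reason,
                    "positive": "" if c.positive is None else str(c.positive),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """threshold -> call -> associate -> enrich, with all outputs on disk.

    Returns the report bundle as a dict; every stage error is re-raised as
    :class:`PipelineError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("ampliclone %s pipeline: %s", __version__, config)

    try:
        reference = read_count_table(config.reference_path)
        model = estimate_background(
            reference,
            k_sigma=config.k_sigma,
            n_trim_each_end=config.n_trim,
            pseudocount=config.pseudocount,
        )
    except (OSError, AmplicloneError) as exc:
        raise PipelineError("threshold", str(exc)) from exc
    model.to_json(out_dir / "model.json")
    log.info("threshold: %.6g (k=%g, n_ref=%d)", model.threshold_fraction,
             model.k_sigma, model.n_reference_used)

    try:
        cohort = read_count_table(config.cohort_path)
        summaries = {
            p: call_cohort(cohort, model, config.min_depth, passage_filter=p)
            for p in config.passages
        }
    except (OSError, AmplicloneError) as exc:
        raise PipelineError("call", str(exc)) from exc
    _calls_frame(summaries).to_csv(out_dir / "calls.tsv", sep="\t", index=False)

    assoc_passage = (
        config.association_passage
        if config.association_passage is not None
        else config.passages[-1]
    )
    try:
        assoc = build_association(summaries[assoc_passage], groups=config.association_groups)
    except AmplicloneError as exc:
        raise PipelineError("associate", str(exc)) from exc
    assoc_dict = {
        "table": list(assoc.table.cells),
        "p_two_sided": assoc.p_two_sided,
        "odds_ratio": assoc.odds_ratio,
        "prevalence_per_group": list(assoc.prevalence_per_group),
        "passage": assoc_passage,
    }
    _dump_json(assoc_dict, out_dir / "assoc.json")

    try:
        series = series_from_table(cohort, passages=config.passages)
        fit_all = fit_enrichment(series, passages=set(config.passages))
        fit_segments = fit_enrichment_segments(series, breakpoints=tuple(config.passages))
    except AmplicloneError as exc:
        raise PipelineError("enrich", str(exc)) from exc
    fits_dict = {
        "all_passages": fit_all.to_dict(),
        "segments": {
            f"{lo}-{hi}": f.to_dict()
            for (lo, hi), f in zip(
                zip(config.passages[:-1], config.passages[1:]), fit_segments
            )
        },
    }
    _dump_json(fits_dict, out_dir / "fit.json")

    positivity = {
        str(p): {
            g: {"evaluable": gc.evaluable, "positive": gc.positive}
            for g, gc in s.groups.items()
        }
        for p, s in summaries.items()
    }
    bundle = {
        "version": __version__,
        "config": {
            "k_sigma": config.k_sigma,
            "n_trim": config.n_trim,
            "pseudocount": config.pseudocount,
            "min_depth": config.min_depth,
            "passages": list(config.passages),
            "association_passage": assoc_passage,
            "seed": config.seed,
        },
        "threshold_fraction": model.threshold_fraction,
        "positivity": positivity,
        "association": assoc_dict,
        "enrichment": fits_dict,
    }
    _dump_json(bundle, out_dir / "summary.json")

    lines = [f"threshold_fraction: {model.threshold_fraction:.6g}"]
    for p, s in summaries.items():
        for g, gc in s.groups.items():
            lines.append(f"passage {p} {g}: {gc.positive}/{gc.evaluable} positive")
    lines.append(
        f"association (passage {assoc_passage}): p={assoc.p_two_sided:.4g} "
        f"OR={assoc.odds_ratio:.3g}"
    )
    lines.append(
        f"enrichment all passages: RR={fit_all.rate_ratio_per_passage:.3f} "
        f"[{fit_all.ci_low:.3f}, {fit_all.ci_high:.3f}] p={fit_all.p_value:.3g}"
    )
    for (lo, hi), f in zip(zip(config.passages[:-1], config.passages[1:]), fit_segments):
        lines.append(
            f"enrichment {lo}p->{hi}p: RR={f.rate_ratio_per_passage:.3f} "
            f"[{f.ci_low:.3f}, {f.ci_high:.3f}] p={f.p_value:.3g}"
        )
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    for line in lines:
        log.info("%s", line)
    return bundle


def render_distribution_report(
    table: CohortTable,
    model: BackgroundModel | None = None,
    out_prefix: str | Path | None = None,
    min_depth: int = 0,
) -> pd.DataFrame:
    """Per-passage box summary (Tukey convention) of allele fractions.

    Returns a data frame with median, quartiles, whiskers at 1.5 * IQR and
    outlier counts; when ``out_prefix`` is given also writes
    ``<prefix>_distribution.tsv`` and ``<prefix>_distribution.png`` (with
    the threshold drawn as a horizontal reference line).
    """
    samples = [s for s in table if s.total_reads >= max(min_depth, 1)]
    if not samples:
        raise EmptyReportError("no samples to report")
    frame = pd.DataFrame(
        {
            "passage": [s.passage for s in samples],
            "fraction": [s.alt_reads / s.total_reads for s in samples],
        }
    )
    rows = []
    groups = {}
    for passage, grp in frame.groupby("passage"):
        v = np.sort(grp["fraction"].to_numpy())
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        in_lo = v[v >= q1 - 1.5 * iqr]
        in_hi = v[v <= q3 + 1.5 * iqr]
        whisker_low = in_lo[0] if in_lo.size else q1
        whisker_high = in_hi[-1] if in_hi.size else q3
        n_outliers = int(((v < whisker_low) | (v > whisker_high)).sum())
        rows.append(
            {
                "passage": passage,
                "n": v.size,
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": whisker_low,
                "whisker_high": whisker_high,
                "n_outliers": n_outliers,
            }
        )
        groups[passage] = v
    stats = pd.DataFrame(rows).sort_values("passage").reset_index(drop=True)

    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        stats.to_csv(f"{out_prefix}_distribution.tsv", sep="\t", index=False)
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        keys = sorted(groups)
        ax.boxplot([groups[k] for k in keys], tick_labels=[f"{k}p" for k in keys], whis=1.5)
        if model is not None:
            ax.axhline(model.threshold_fraction, color="black", lw=1)
        ax.set_yscale("log")
        ax.set_xlabel("passage")
        ax.set_ylabel("allele fraction")
        fig.tight_layout()
        fig.savefig(f"{out_prefix}_distribution.png", dpi=150)
        plt.close(fig)
    return stats
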