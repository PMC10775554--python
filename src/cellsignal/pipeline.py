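"""End-to-end experiment runner driven by a single declarative YAML config.

Two experiment shapes are supported:

* **pan analysis** — fit every bulk sample under a ladder of progressively
  more complete references (group subsets as stages), then summarise group
  contributions per cohort and compare foetalness between childhood and adult
  cohorts at the full reference.
* **tissue analysis** — fit a fine-grained tissue reference (e.g. foetal vs
  adult hepatocyte), optionally refit with named genes dropped, and regress a
  named contribution on a named gene's log10 TPM (ordinary least squares with
  pseudocount 1e-2), the marker-correlation design.

All outputs are TSV; every table carries the package version and a config
hash in a leading comment line so reruns are attributable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from . import __version__
from .cell_signal import SignalFit, fit_signals, progressive_fit, summarize_groups
from .io_formats import read_bulk_samples, read_gene_lengths, read_mtx_bundle, tpm_transform
from .reference_builder import (
    ReferenceDataset,
    ReferenceProfileSet,
    build_profiles,
    load_reference,
)

logger = logging.getLogger("cellsignal")


class ConfigError(ValueError):
    """Raised when a run config fails validation, before any compute."""


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    raw: dict[str, Any]
    base_dir: Path
    output_dir: Path
    seed: int = 0
    config_hash: str = ""

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        cfg = RunConfig(
            raw=raw,
            base_dir=path.parent,
            output_dir=Path(raw.get("output_dir", "cellsignal_out")),
            seed=int(raw.get("seed", 0)),
            config_hash=hashlib.sha1(
                json.dumps(raw, sort_keys=True, default=str).encode()
            ).hexdigest()[:12],
        )
        if not cfg.output_dir.is_absolute():
            cfg.output_dir = cfg.base_dir / cfg.output_dir
        cfg.validate()
        return cfg

    def _resolve(self, p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else self.base_dir / q

    def validate(self) -> None:
        ref = self.raw.get("reference")
        if not ref:
            raise ConfigError("config needs a 'reference' section")
        if "dir" not in ref and not ref.get("datasets"):
            raise ConfigError("reference needs 'dir' (prebuilt) or 'datasets'")
        for ds in ref.get("datasets", []):
            if not self._resolve(ds["dir"]).exists():
                raise ConfigError(f"reference dataset dir missing: {ds['dir']}")
        bulk = self.raw.get("bulk")
        if not bulk or "counts" not in bulk:
            raise ConfigError("config needs bulk.counts")
        if not self._resolve(bulk["counts"]).exists():
            raise ConfigError(f"bulk counts file missing: {bulk['counts']}")
        manifest = bulk.get("manifest")
        if manifest is not None:
            mpath = self._resolve(manifest)
            if not mpath.exists():
                raise ConfigError(f"bulk manifest missing: {manifest}")
            mdf = pd.read_csv(mpath, sep="\t")
            if mdf.empty:
                raise ConfigError("bulk manifest is empty")
        stages = self.raw.get("stages", {})
        declared = {"early_embryo", "gastrulation", "foetal", "adult"}
        for name, groups in stages.items():
            bad = set(groups) - declared
            if bad:
                raise ConfigError(f"stage {name!r} references unknown groups {sorted(bad)}")

    # -- loading -----------------------------------------------------------

    def load_reference(self) -> ReferenceProfileSet:
        ref = self.raw["reference"]
        if "dir" in ref:
            reference = load_reference(self._resolve(ref["dir"]))
        else:
            datasets = []
            for ds in ref["datasets"]:
                d = self._resolve(ds["dir"])
                mat, feats, _ = read_mtx_bundle(
                    d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv"
                )
                ann = pd.read_csv(d / "annotation.tsv", sep="\t")
                lengths = (
                    read_gene_lengths(self._resolve(ds["lengths"])).to_numpy()
                    if ds.get("lengths")
                    else None
                )
                datasets.append(
                    ReferenceDataset(
                        counts=mat,
                        gene_ids=feats["gene_id"].tolist(),
                        symbols=feats["symbol"].tolist() if "symbol" in feats else None,
                        annotation=ann,
                        chemistry=ds.get("chemistry", "umi"),
                        gene_lengths=lengths,
                    )
                )
            hk = ref.get("housekeeping")
            hk_list = (
                [l.strip() for l in self._resolve(hk).read_text().splitlines() if l.strip()]
                if hk
                else None
            )
            reference = build_profiles(
                datasets,
                exclude_mito_ribo=bool(ref.get("exclude_mito_ribo", False)),
                housekeeping_genes=hk_list,
            )
        for rule in ref.get("exclude", []):
            reference = reference.exclude_where(
                lambda row, rule=rule: all(
                    str(row.get(k, "")) == str(v) for k, v in rule.items()
                )
            )
        return reference

    def load_bulk(self):
        bulk = self.raw["bulk"]
        manifest = None
        if bulk.get("manifest"):
            manifest = pd.read_csv(self._resolve(bulk["manifest"]), sep="\t")
        samples = read_bulk_samples(
            self._resolve(bulk["counts"]),
            self._resolve(bulk["lengths"]) if bulk.get("lengths") else None,
            manifest,
        )
        if not samples:
            raise ConfigError("bulk manifest selects zero samples")
        return samples

    def stages(self) -> dict[str, list[str]]:
        return dict(self.raw.get("stages", {})) or {
            "full": ["early_embryo", "gastrulation", "foetal", "adult"]
        }


# ---------------------------------------------------------------------------
# output helpers
# ---------------------------------------------------------------------------

def _write_table(path: Path, df: pd.DataFrame, config: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# cellsignal {__version__} config={config.config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_result_table(path: str | Path) -> pd.DataFrame:
    """Read a pipeline output table, skipping the provenance comment line."""
    return pd.read_csv(path, sep="\t", comment="#")


def _fit_rows(fit: SignalFit) -> list[dict]:
    rows = [
        {
            "sample_id": fit.sample_id,
            "stage": fit.stage,
            "cell_type": ct,
            "contribution": float(v),
        }
        for ct, v in fit.contributions.items()
    ]
    rows.append(
        {
            "sample_id": fit.sample_id,
            "stage": fit.stage,
            "cell_type": "intercept",
            "contribution": fit.intercept,
        }
    )
    return rows


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def run_pan_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Progressive-reference fits, cohort summaries, foetalness comparison.

    Returns (and writes) four tables: per-sample x stage contributions,
    per-sample summaries, per-cohort x stage mean group contributions, and
    the full-reference foetalness comparison by age class. Failed fits are
    collected in a run report rather than silently dropped.
    """
    reference = config.load_reference()
    samples = config.load_bulk()
    stages = config.stages()
    drop = config.raw.get("drop_genes") or None

    contrib_rows: list[dict] = []
    summary_rows: list[dict] = []
    failures: list[dict] = []
    last_stage = list(stages)[-1]
    for sample in samples:
        try:
            fits = progressive_fit(sample, reference, stages, drop_genes=drop)
        except Exception as exc:  # surfaced in the run report
            logger.error("fit failed for %s: %s", sample.sample_id, exc)
            failures.append({"sample_id": sample.sample_id, "error": str(exc)})
            continue
        for fit, (stage_name, groups) in zip(fits, stages.items()):
            contrib_rows.extend(_fit_rows(fit))
            sub = reference.subset_types(
                [ct for ct in reference.cell_types if reference.group_of(ct) in set(groups)]
            )
            score = summarize_groups(fit, sub)
            summary_rows.append(
                {
                    "sample_id": sample.sample_id,
                    "stage": stage_name,
                    "cohort": sample.cohort,
                    "age_class": sample.age_class,
                    "pseudo_r2": fit.pseudo_r2,
                    "unexplained": score.unexplained,
                    "embryoness": score.embryoness,
                    "foetalness": score.foetalness,
                    "adultness": score.adultness,
                    "converged": fit.converged,
                }
            )
    contributions = pd.DataFrame(contrib_rows)
    summary = pd.DataFrame(summary_rows)
    if summary.empty:
        raise RuntimeError("every fit failed; see the run report")
    cohort_means = (
        summary.groupby(["cohort", "stage"], sort=True)[
            ["embryoness", "foetalness", "adultness", "unexplained", "pseudo_r2"]
        ]
        .mean()
        .reset_index()
    )
    foetalness = summary.loc[
        summary["stage"] == last_stage,
        ["sample_id", "cohort", "age_class", "foetalness", "adultness", "unexplained"],
    ].reset_index(drop=True)
    report = pd.DataFrame(failures, columns=["sample_id", "error"])

    out = config.output_dir
    tables = {
        "contributions": contributions,
        "summary": summary,
        "cohort_means": cohort_means,
        "foetalness_by_age": foetalness,
        "run_report": report,
    }
    for name, df in tables.items():
        _write_table(out / f"{name}.tsv", df, config)
    return tables


def run_tissue_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Fine-grained tissue fits plus the marker-gene trend analysis.

    The optional ``trend`` section names a contribution (cell type) and a
    gene; the named contribution is regressed on log10(TPM + 1e-2) of that
    gene by ordinary least squares. When ``trend.drop_genes`` is present the
    contributions come from a refit excluding those genes, so the trend is
    not driven by the marker itself.
    """
    reference = config.load_reference()
    samples = config.load_bulk()
    trend_cfg = config.raw.get("trend") or {}
    drop = trend_cfg.get("drop_genes") or config.raw.get("drop_genes") or None

    contrib_rows: list[dict] = []
    failures: list[dict] = []
    fits: dict[str, SignalFit] = {}
    for sample in samples:
        try:
            fit = fit_signals(sample, reference, drop_genes=drop, stage="tissue")
        except Exception as exc:
            logger.error("fit failed for %s: %s", sample.sample_id, exc)
            failures.append({"sample_id": sample.sample_id, "error": str(exc)})
            continue
        fits[sample.sample_id] = fit
        contrib_rows.extend(_fit_rows(fit))
    contributions = pd.DataFrame(contrib_rows)
    if not fits:
        raise RuntimeError("every fit failed; see the run report")

    tables: dict[str, pd.DataFrame] = {
        "contributions": contributions,
        "run_report": pd.DataFrame(failures, columns=["sample_id", "error"]),
    }

    if trend_cfg:
        ct = trend_cfg["contribution"]
        gene = trend_cfg["gene"]
        if ct not in reference.cell_types:
            raise ConfigError(f"trend contribution {ct!r} not a reference cell type")
        rows = []
        for sample in samples:
            if sample.sample_id not in fits:
                continue
            if gene not in sample.counts.index:
                raise ConfigError(f"trend gene {gene!r} absent from bulk data")
            tpm = tpm_transform(sample.counts, sample.lengths)[gene]
            rows.append(
                {
                    "sample_id": sample.sample_id,
                    "contribution": float(fits[sample.sample_id].contributions[ct]),
                    "log10_tpm": float(np.log10(tpm + 1e-2)),
                }
            )
        trend = pd.DataFrame(rows)
        res = scipy.stats.linregress(trend["log10_tpm"], trend["contribution"])
        tables["trend_points"] = trend
        tables["trend_summary"] = pd.DataFrame(
            [
                {
                    "cell_type": ct,
                    "gene": gene,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "r_squared": res.rvalue**2,
                    "p_value": res.pvalue,
                    "n": len(trend),
                }
            ]
        )

    for name, df in tables.items():
        _write_table(config.output_dir / f"{name}.tsv", df, config)
    return tables
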