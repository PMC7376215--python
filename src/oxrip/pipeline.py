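"""End-to-end orchestration: enrichment in both conditions, discrimination,
overlap-ready induced table, selectivity, differential expression and
pathway over-representation, with a JSON provenance manifest.

Every stage writes its table as canonical TSV into the output directory;
the manifest records input checksums, the configuration, package version
and per-stage summaries.  Reruns on identical inputs reproduce identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import oxrip
from oxrip.contrasts import diff_expression, rip_enrichment
from oxrip.induced_set import discriminate_induced
from oxrip.io_formats import read_counts, read_gmt, read_sample_sheet, write_results
from oxrip.pathway_enrich import fisher_overrepresentation
from oxrip.selectivity import assign_expression_bins, downreg_concordance, selectivity_profile


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Paths, thresholds and options for a full pipeline run."""

    counts_path: str
    samples_path: str
    out_dir: str
    gmt_path: str | None = None
    padj_exposed: float = 0.1
    padj_control: float = 0.1
    min_fc: float = 2.0
    ratio_threshold: float = 1.5
    de_padj: float = 0.05
    up_fc: float = 2.0
    down_fc: float = 0.5
    n_bins: int = 10
    bin_scheme: str = "equal_count"
    min_mean: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("padj_exposed", "padj_control", "de_padj"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]: {v}")
        if self.min_fc <= 0 or self.ratio_threshold <= 0:
            raise ValueError("fold-change thresholds must be positive")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full inference and return the manifest (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "oxrip",
        "version": oxrip.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {},
        "outputs": {},
        "summary": {},
    }
    for key in ("counts_path", "samples_path", "gmt_path"):
        path = getattr(config, key)
        if path is not None:
            if not Path(path).exists():
                raise FileNotFoundError(f"{key} does not exist: {path}")
            manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}

    def _write(name: str, table: pd.DataFrame, index: bool = True) -> None:
        path = out_dir / name
        out = table.reset_index() if index else table
        write_results(out, path)
        manifest["outputs"][name] = str(path)

    try:
        samples = read_sample_sheet(config.samples_path)
        counts = read_counts(config.counts_path, samples)
    except Exception as exc:  # noqa: BLE001 - wrap with stage provenance
        raise StageError("load_inputs", exc) from exc

    try:
        table_exp, enriched_exp = rip_enrichment(
            counts, "exposed", padj_max=config.padj_exposed,
            min_fc=config.min_fc, min_mean=config.min_mean,
        )
        table_ctl, enriched_ctl = rip_enrichment(
            counts, "control", padj_max=config.padj_control,
            min_fc=config.min_fc, min_mean=config.min_mean,
        )
        _write("enrichment_exposed.tsv", table_exp)
        _write("enrichment_control.tsv", table_ctl)
        manifest["summary"]["n_enriched_exposed"] = len(enriched_exp)
        manifest["summary"]["n_enriched_control"] = len(enriched_ctl)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        _fail_marker(out_dir, "rip_enrichment", exc)
        raise StageError("rip_enrichment", exc) from exc

    try:
        induced = discriminate_induced(enriched_exp, enriched_ctl, config.ratio_threshold)
        _write("induced.tsv", induced.members)
        manifest["summary"]["n_induced"] = len(induced)
        manifest["summary"]["min_log2fc_induced"] = _json_float(induced.min_log2fc)
    except Exception as exc:  # noqa: BLE001
        _fail_marker(out_dir, "discriminate_induced", exc)
        raise StageError("discriminate_induced", exc) from exc

    try:
        de = diff_expression(
            counts, padj_max=config.de_padj, up_fc=config.up_fc,
            down_fc=config.down_fc, min_mean=config.min_mean,
        )
        _write("diffexpr.tsv", de.table)
        manifest["summary"]["n_de_up"] = len(de.up)
        manifest["summary"]["n_de_down"] = len(de.down)
    except Exception as exc:  # noqa: BLE001
        _fail_marker(out_dir, "diff_expression", exc)
        raise StageError("diff_expression", exc) from exc

    try:
        base_means = de.table["base_mean"]
        bins = assign_expression_bins(base_means, config.n_bins, config.bin_scheme)
        profile = selectivity_profile(bins, base_means, induced.transcript_ids & set(bins.index))
        _write("selectivity.tsv", profile.table, index=False)
        manifest["summary"]["selectivity_chi2"] = _json_float(profile.chi2)
        manifest["summary"]["selectivity_pvalue"] = _json_float(profile.pvalue)
        concordance = downreg_concordance(sorted(induced.transcript_ids), de)
        manifest["summary"]["downreg_concordance"] = {
            k: _json_float(v) for k, v in concordance.items()
        }
    except Exception as exc:  # noqa: BLE001
        _fail_marker(out_dir, "selectivity", exc)
        raise StageError("selectivity", exc) from exc

    if config.gmt_path is not None:
        try:
            sets = read_gmt(config.gmt_path)
            universe = frozenset(de.table.index[de.table["base_mean"] > 0])
            query = induced.transcript_ids & universe
            pathways = fisher_overrepresentation(query, sets, universe)
            _write("pathways.tsv", pathways, index=False)
            top = pathways.head(5)["set_name"].tolist() if len(pathways) else []
            manifest["summary"]["top_pathways"] = top
        except Exception as exc:  # noqa: BLE001
            _fail_marker(out_dir, "pathway_enrich", exc)
            raise StageError("pathway_enrich", exc) from exc

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"]["manifest.json"] = str(manifest_path)
    return manifest


def _json_float(value) -> float | int | None:
    if isinstance(value, (int, np.integer)):
        return int(value)
    value = float(value)
    return None if np.isnan(value) else value


def _fail_marker(out_dir: Path, stage: str, exc: Exception) -> None:
    (out_dir / "FAILED").write_text(f"{stage}: {exc}\n", encoding="utf-8")
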