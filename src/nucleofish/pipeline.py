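"""Orchestration: stacks -> segmentation -> geometry -> allele table -> stats.

The pipeline never silently drops a signal: every nucleus or spot that
cannot be measured is recorded in the exclusion log with a reason, and the
QC report mirrors the bookkeeping a careful imaging study keeps — the
fraction of signals measured at negative distances (outside the chromatin
mask) and the fraction of nuclei processed with the ellipsoid fallback.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry, segmentation, stats
from .schema import ALLELE_COLUMNS, EXPECTED_ALLELES, GENOTYPES, coerce_allele_table
from .segmentation import ROI, SpotParams
from .stack import ImageStack

log = logging.getLogger("nucleofish.pipeline")


class SchemaError(ValueError):
    """An allele table does not conform to the documented schema."""


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; paths may be None in in-memory use."""

    stacks_dir: str | None = None
    roi_file: str | None = None
    table_file: str | None = None        # stats-only entry point
    out_dir: str | None = None
    counterstain: str = "dapi"
    dna_channel: str = "dna_fish"
    rna_channel: str | None = "rna_fish"
    smooth_sigma: float = 1.0
    spot_k_sigma: float = 5.0
    min_spot_voxels: int = 4
    pairing_radius: float = 1.5
    expression_radius_um: float = 0.5
    expression_k_sigma: float = 3.0
    fallback_solidity: float | None = None   # auto ellipsoid-fallback trigger
    analyses: list[str] = field(default_factory=lambda: ["summary"])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smooth_sigma < 0 or self.spot_k_sigma <= 0:
            raise ValueError("invalid segmentation parameters")
        if self.pairing_radius <= 0 or self.expression_radius_um <= 0:
            raise ValueError("radii must be positive")
        if self.fallback_solidity is not None and not 0 < self.fallback_solidity <= 1:
            raise ValueError("fallback_solidity must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class QCReport:
    """Measurement bookkeeping across a pipeline run."""

    n_records: int = 0
    n_negative: int = 0
    n_fallback_nuclei: int = 0
    n_nuclei: int = 0
    exclusions: list[dict] = field(default_factory=list)

    @property
    def negative_fraction(self) -> float:
        return self.n_negative / self.n_records if self.n_records else 0.0

    @property
    def fallback_fraction(self) -> float:
        return self.n_fallback_nuclei / self.n_nuclei if self.n_nuclei else 0.0

    @property
    def n_excluded(self) -> int:
        return len(self.exclusions)

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_nuclei": self.n_nuclei,
            "negative_fraction": self.negative_fraction,
            "fallback_fraction": self.fallback_fraction,
            "n_excluded": self.n_excluded,
            "exclusions": self.exclusions,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# Per-nucleus measurement
# ---------------------------------------------------------------------------

def measure_nucleus(stack: ImageStack, roi: ROI, genotype: str,
                    config: PipelineConfig, qc: QCReport,
                    use_fallback: bool = False,
                    cell_id: str | None = None,
                    line_id: str | None = None) -> list[dict]:
    """Measure all alleles of one nucleus; returns allele-table rows.

    Failures and excess signals append to the QC exclusion log rather than
    raising, so one bad nucleus cannot abort a run.
    """
    if genotype not in GENOTYPES:
        raise SchemaError(f"unknown genotype {genotype!r}")
    cell_id = cell_id or f"{roi.stack_id}_{roi.nucleus_id}"
    line_id = line_id or genotype

    mask = segmentation.binarize_nucleus(
        stack, roi, counterstain=config.counterstain,
        smooth_sigma=config.smooth_sigma)
    qc.n_nuclei += 1
    if not use_fallback and config.fallback_solidity is not None:
        use_fallback = mask.solidity < config.fallback_solidity
    if use_fallback:
        mask = geometry.ellipsoid_fallback(mask)
        qc.n_fallback_nuclei += 1

    spots = segmentation.detect_spots(
        stack, config.dna_channel,
        SpotParams(k_sigma=config.spot_k_sigma,
                   min_voxels=config.min_spot_voxels),
        roi=roi)
    groups = segmentation.merge_replication_doublets(
        spots, EXPECTED_ALLELES[genotype], config.pairing_radius)

    shells = geometry.equal_volume_shells(mask)
    rows: list[dict] = []
    kept = 0
    for gi, group in enumerate(groups):
        if group.excess:
            qc.exclusions.append({
                "stack_id": roi.stack_id, "nucleus_id": roi.nucleus_id,
                "reason": "excess signals after doublet merging",
            })
            log.warning("%s/%s: excess signal excluded", roi.stack_id,
                        roi.nucleus_id)
            continue
        # duplicated-signal rule: distances are measured per member first,
        # then averaged into one allele record
        ds = [geometry.signed_border_distance(s.centroid_um, mask)
              for s in group.spots]
        rs = [geometry.local_radius(s.centroid_um, mask) for s in group.spots]
        d = float(np.mean(ds))
        r = float(np.mean(rs))
        expressed = False
        if config.rna_channel and config.rna_channel in stack.channels:
            expressed = segmentation.classify_expression(
                stack, config.rna_channel, group.centroid_um, mask,
                radius_um=config.expression_radius_um,
                k_sigma=config.expression_k_sigma)
        rows.append({
            "cell_id": cell_id, "line_id": line_id, "genotype": genotype,
            "allele_id": f"a{kept + 1}",
            "distance_um": round(d, 3),
            "local_radius_um": round(r, 3),
            "relative_distance": round(geometry.relative_distance(d, r), 3)
            if r > 0 else np.nan,
            "shell": shells.assign(d),
            "near_far": "single",
            "expressed": expressed,
            "fallback": mask.provenance == "ellipsoid-fallback",
            "volume_um3": round(mask.volume_um3, 3),
        })
        kept += 1
        qc.n_records += 1
        if d < 0:
            qc.n_negative += 1
    return rows


def measure_stacks(items, config: PipelineConfig) -> tuple[pd.DataFrame, QCReport]:
    """Measure a sequence of ``(stack, roi, genotype)`` triples.

    Per-nucleus errors are logged and appended to the exclusion list; the
    run fails only if no nucleus succeeds.
    """
    qc = QCReport()
    rows: list[dict] = []
    n_attempted = 0
    for stack, roi, genotype in items:
        n_attempted += 1
        try:
            cell_rows = measure_nucleus(stack, roi, genotype, config, qc)
        except Exception as err:  # per-item failure is logged, not fatal
            qc.exclusions.append({
                "stack_id": getattr(roi, "stack_id", "?"),
                "nucleus_id": getattr(roi, "nucleus_id", "?"),
                "reason": f"{type(err).__name__}: {err}",
            })
            log.error("nucleus failed: %s", err)
            continue
        if cell_rows:
            ranked = geometry.assign_near_far(pd.DataFrame(cell_rows))
            rows.extend(ranked.drop(columns=["tie"]).to_dict("records"))
    if n_attempted and not rows:
        raise RuntimeError("no nucleus could be measured; see exclusion log")
    table = (coerce_allele_table(pd.DataFrame(rows, columns=list(ALLELE_COLUMNS)))
             if rows else pd.DataFrame(columns=list(ALLELE_COLUMNS)))
    return table, qc


# ---------------------------------------------------------------------------
# Table validation (pipeline output or external raw-data tables)
# ---------------------------------------------------------------------------

def validate_table(table: pd.DataFrame,
                   column_mapping: dict[str, str] | str | Path | None = None
                   ) -> pd.DataFrame:
    """Validate (and optionally rename into) the allele-table schema.

    ``column_mapping`` maps external column names to schema names, given
    directly or as a YAML file, so externally produced measurement tables
    can be ingested.  Raises :class:`SchemaError` listing any missing
    mandatory column, unknown genotype labels, or physical-unit
    violations (non-positive volumes or local radii).
    """
    df = table.copy()
    if column_mapping is not None:
        if not isinstance(column_mapping, dict):
            column_mapping = yaml.safe_load(Path(column_mapping).read_text())
        df = df.rename(columns=column_mapping)
    missing = [c for c in ALLELE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    try:
        df = coerce_allele_table(df[list(ALLELE_COLUMNS)])
    except (ValueError, TypeError) as err:
        raise SchemaError(f"dtype coercion failed: {err}") from err
    bad_geno = sorted(set(df["genotype"]) - set(GENOTYPES))
    if bad_geno:
        raise SchemaError(f"unknown genotype labels: {bad_geno}")
    if (df["volume_um3"] <= 0).any():
        raise SchemaError("non-positive nuclear volume (expected um^3 > 0)")
    if (df["local_radius_um"] <= 0).any():
        raise SchemaError("non-positive local radius (expected um > 0)")
    bad_shell = sorted(set(df["shell"]) - set(geometry.SHELLS))
    if bad_shell:
        raise SchemaError(f"unknown shell labels: {bad_shell}")
    return df


# ---------------------------------------------------------------------------
# Analysis battery
# ---------------------------------------------------------------------------

def _contingency(table: pd.DataFrame, rows: str, cols: str,
                 row_order, col_order) -> np.ndarray:
    ct = pd.crosstab(table[rows], table[cols])
    ct = ct.reindex(index=row_order, columns=col_order, fill_value=0)
    return ct.to_numpy()


def run_analyses(table: pd.DataFrame, analyses: list[str]) -> tuple[dict, str]:
    """Run the requested statistical analyses on a validated allele table.

    Returns a dict of results keyed by analysis name and a plain-text
    report.  Analyses silently narrow to the genotypes present.
    """
    results: dict[str, object] = {}
    lines: list[str] = []

    def section(title: str) -> None:
        lines.extend(["", "=" * 8 + f" {title} " + "=" * 8])

    for name in analyses:
        if name == "summary":
            section("group summaries (signed distance, um)")
            summ = stats.summarize_groups(table)
            results["summary"] = summ
            lines.append(summ.to_string(index=False))
            states = stats.expression_state_counts(table)
            results["expression_states"] = states
            lines.append("")
            lines.append("cells per line by expression state:")
            lines.append(states.to_string(index=False))
        elif name == "parental":
            sub = table[table["genotype"].isin(["matrepKO", "patrepKO"])]
            section("parental origin: maternal vs paternal alleles")
            res = stats.fit_distance_model(sub, predictor="genotype")
            results["parental"] = res
            lines.append(res.summary())
        elif name == "epigenotype":
            keep = [g for g in ("WT2", "Zfp57KO", "matIGDMRKO")
                    if g in set(table["genotype"])]
            sub = table[table["genotype"].isin(keep)]
            section("epigenotype switch vs matched WT")
            res = stats.fit_distance_model(sub, predictor="genotype",
                                           reference="WT2" if "WT2" in keep else None)
            results["epigenotype"] = res
            lines.append(res.summary())
        elif name == "nearfar":
            section("near vs far allele within WT cells")
            sub = table[(table["genotype"].isin(["WT", "WT2"]))
                        & (table["near_far"].isin(["near", "far"]))]
            res = stats.fit_distance_model(sub, predictor="near_far")
            results["nearfar"] = res
            lines.append(res.summary())
            for g in ("WT", "Zfp57KO"):
                sub_g = table[(table["genotype"] == g)
                              & (table["near_far"].isin(["near", "far"]))]
                if sub_g.empty:
                    continue
                ct = _contingency(sub_g, "near_far", "expressed",
                                  ["near", "far"], [True, False])
                log2_or, p = stats.fisher_near_far(ct)
                results[f"fisher_{g}"] = (log2_or, p)
                lines.append(f"{g}: near/far x expressed Fisher test: "
                             f"log2(OR) = {log2_or:.2f}, p = {p:.2f}")
        elif name == "expression":
            section("does distance predict expression?")
            for g, cluster in (("patrepKO", False), ("Zfp57KO", True)):
                sub = table[table["genotype"] == g]
                if sub.empty or sub["expressed"].nunique() < 2:
                    continue
                res = stats.fit_expression_model(sub, cluster=cluster)
                results[f"expression_{g}"] = res
                lines.append(f"[{g}]")
                lines.append(res.summary())
            zf = table[table["genotype"] == "Zfp57KO"]
            if not zf.empty:
                res = stats.fit_mixed_distance_model(zf)
                results["expression_count_mixed"] = res
                lines.append("[Zfp57KO, distance ~ expressed-allele count]")
                lines.append(res.summary())
        elif name == "shells":
            section("peripheral enrichment of non-expressed maternal(ised) alleles")
            sub = table[table["genotype"].isin(["patrepKO", "Zfp57KO"])]
            if not sub.empty:
                ct3 = _contingency(sub, "expressed", "shell",
                                   [True, False], ["outer", "middle", "inner"])
                chi2, df, p = stats.shell_chisq(ct3)
                results["shell_chisq"] = (chi2, df, p)
                lines.append(f"expressed x shell: chi2 = {chi2:.4f}, "
                             f"df = {df}, p = {p:.3f}")
                sub = sub.assign(beyond=sub["distance_um"] > 0.5)
                ct2 = _contingency(sub, "expressed", "beyond",
                                   [True, False], [True, False])
                chi2, df, p = stats.shell_chisq(ct2)
                results["threshold_chisq"] = (chi2, df, p)
                lines.append(f"expressed x (> 0.5 um from border): "
                             f"chi2 = {chi2:.2f}, df = {df}, p = {p:.3f}")
        else:
            raise ValueError(f"unknown analysis {name!r}")
    return results, "\n".join(lines).strip()


# ---------------------------------------------------------------------------
# File-level entry point
# ---------------------------------------------------------------------------

def read_roi_file(path: str | Path) -> pd.DataFrame:
    """ROI CSV: stack_id, nucleus_id, genotype[, line_id], z0,z1,y0,y1,x0,x1."""
    df = pd.read_csv(path)
    needed = ["stack_id", "nucleus_id", "genotype",
              "z0", "z1", "y0", "y1", "x0", "x1"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"ROI file missing columns: {missing}")
    return df


def run_pipeline(config: PipelineConfig) -> tuple[pd.DataFrame, QCReport, str]:
    """Full run from files: returns (allele table, QC report, text report).

    In stats-only mode (``table_file`` set) the measurement stage is
    skipped and the analyses run on the validated external table.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    if config.table_file:
        table = validate_table(pd.read_csv(config.table_file))
        qc = QCReport(n_records=len(table),
                      n_negative=int((table["distance_um"] < 0).sum()),
                      n_nuclei=int(table["cell_id"].nunique()),
                      n_fallback_nuclei=int(
                          table.loc[table["fallback"], "cell_id"].nunique()))
    else:
        if not config.stacks_dir or not config.roi_file:
            raise ValueError("need stacks_dir + roi_file, or table_file")
        rois = read_roi_file(config.roi_file)
        stacks: dict[str, ImageStack] = {}
        for path in sorted(Path(config.stacks_dir).glob("*.tif*")):
            st = ImageStack.read_tiff(path)
            stacks[st.stack_id] = st
        items = []
        for _, r in rois.iterrows():
            if r.stack_id not in stacks:
                log.error("ROI references unknown stack %s", r.stack_id)
                continue
            roi = ROI(r.stack_id, str(r.nucleus_id), int(r.z0), int(r.z1),
                      int(r.y0), int(r.y1), int(r.x0), int(r.x1))
            items.append((stacks[r.stack_id], roi, r.genotype))
        table, qc = measure_stacks(items, config)

    analyses = [a for a in config.analyses if a]
    results, report = run_analyses(table, analyses) if analyses else ({}, "")

    if out_dir:
        table.to_csv(out_dir / "allele_table.csv", index=False)
        qc.write_json(out_dir / "qc_report.json")
        (out_dir / "analysis_report.txt").write_text(report + "\n")
        for key, val in results.items():
            if isinstance(val, stats.ModelResult):
                val.terms.to_csv(out_dir / f"model_{key}.csv")
    return table, qc, report
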