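"""One-shot orchestration of the full analysis with a run manifest.

Stages: descriptor computation -> barcoding -> class aggregation ->
abundance/constancy filtering -> Poisson-GLM time-course test with
BH-FDR -> kinetic profiling and PCA. Each stage's table is written to
the output directory and is individually re-runnable; the manifest
records the full configuration (defaults included) and package versions
so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .barcoding import DEFAULT_SCHEME, IntervalScheme, assign_barcode
from .differential import call_significant, time_course_test
from .filters import apply_filters
from .io_aggregate import ClassAbundanceMatrix, build_class_matrix, read_psm_table
from .profiling import classify_profiles, profile_pca, summarize_profiles
from .properties import DEFAULT_CONFIG, DESCRIPTOR_ORDER, PropertyConfig, \
    compute_property_vector

__all__ = ["RunConfig", "RunResult", "run_all", "properties_table"]


@dataclass(frozen=True)
class RunConfig:
    """Defaults reproduce the reference analysis settings exactly."""

    property_config: PropertyConfig = DEFAULT_CONFIG
    scheme: IntervalScheme = DEFAULT_SCHEME
    min_spectra: int = 5
    min_variation: float = 0.5
    abundance_mode: str = "max"
    alpha: float = 0.01
    quasipoisson: bool = False
    rho_threshold: float = 0.5


@dataclass
class RunResult:
    properties: pd.DataFrame
    barcodes: pd.Series
    matrix: ClassAbundanceMatrix
    filter_report: pd.DataFrame
    differential: pd.DataFrame
    profiles: pd.DataFrame
    profile_summary: pd.DataFrame
    pca_scores: pd.DataFrame | None
    pca_loadings: pd.DataFrame | None
    manifest: dict


def properties_table(
    sequences, config: PropertyConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Nine-descriptor table for an iterable of sequences."""
    rows = [compute_property_vector(s, config).as_dict() for s in sequences]
    out = pd.DataFrame(rows, index=pd.Index(sequences, name="sequence"))
    return out[list(DESCRIPTOR_ORDER)]


def _config_manifest(config: RunConfig) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {
                f.name: encode(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            }
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    payload = encode(config)
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()
    return {"config": payload, "config_sha256": digest}


def run_all(
    psm, config: RunConfig = RunConfig(), out_dir=None
) -> RunResult:
    """Run every stage on an observation table (path or DataFrame).

    With *out_dir* set, writes one TSV per stage plus ``manifest.json``.
    A stage failure aborts with the stage name and cause.
    """
    stage = "read"
    try:
        if isinstance(psm, (str, Path)):
            records = read_psm_table(psm)
        else:
            from .io_aggregate import aggregate_psm

            records = aggregate_psm(psm)

        stage = "properties"
        sequences = sorted(records["sequence"].unique())
        props = properties_table(sequences, config.property_config)

        stage = "barcode"
        vectors = {
            seq: compute_property_vector(seq, config.property_config)
            for seq in sequences
        }
        barcodes = pd.Series(
            {seq: assign_barcode(v, config.scheme) for seq, v in vectors.items()},
            name="class",
        )
        barcodes.index.name = "sequence"

        stage = "aggregate"
        matrix = build_class_matrix(records, barcodes.to_dict())

        stage = "filter"
        outcome = apply_filters(
            matrix,
            min_spectra=config.min_spectra,
            min_variation=config.min_variation,
            abundance_mode=config.abundance_mode,
        )

        stage = "differential"
        diff = time_course_test(
            outcome.testable,
            alpha=config.alpha,
            quasipoisson=config.quasipoisson,
        )
        significant = call_significant(diff, config.alpha)

        stage = "profile"
        profiles = classify_profiles(
            matrix,
            significant=significant,
            constant=outcome.constant,
            rho_threshold=config.rho_threshold,
        )
        summary = summarize_profiles(profiles, matrix)

        stage = "pca"
        selected_peptides: list[str] = []
        peptide_labels: dict[str, str] = {}
        for cls in profiles.index:
            for seq in matrix.members.get(cls, ()):
                if seq not in peptide_labels:
                    peptide_labels[seq] = profiles.loc[cls, "label"]
                    selected_peptides.append(seq)
        pca_scores = pca_loadings = None
        if len(selected_peptides) >= 3:
            sel_props = props.loc[selected_peptides]
            pca = profile_pca(
                sel_props, pd.Series(peptide_labels, name="label")
            )
            pca_scores = pca.scores.assign(label=pca.labels)
            pca_loadings = pca.loadings
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = _config_manifest(config)
    manifest["pepkin_version"] = __version__
    manifest["stages"] = [
        "properties", "barcodes", "class_matrix", "filter_report",
        "differential", "profiles",
    ]
    manifest["n_peptides"] = len(sequences)
    manifest["n_classes"] = len(matrix.classes)
    manifest["n_significant"] = len(significant)

    result = RunResult(
        properties=props,
        barcodes=barcodes,
        matrix=matrix,
        filter_report=outcome.report,
        differential=diff,
        profiles=profiles,
        profile_summary=summary,
        pca_scores=pca_scores,
        pca_loadings=pca_loadings,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.properties.to_csv(out_dir / "properties.tsv", sep="\t")
    result.barcodes.to_frame().to_csv(out_dir / "barcodes.tsv", sep="\t")
    result.matrix.to_tsv(
        out_dir / "class_matrix.tsv", out_dir / "class_members.tsv"
    )
    result.filter_report.to_csv(out_dir / "filter_report.tsv", sep="\t")
    result.differential.to_csv(out_dir / "differential.tsv", sep="\t")
    result.profiles.to_csv(out_dir / "profiles.tsv", sep="\t")
    result.profile_summary.to_csv(out_dir / "profile_summary.tsv", sep="\t")
    if result.pca_scores is not None:
        result.pca_scores.to_csv(out_dir / "pca_scores.tsv", sep="\t")
        result.pca_loadings.to_csv(out_dir / "pca_loadings.tsv", sep="\t")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
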