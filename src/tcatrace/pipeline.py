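"""File I/O, configuration and stage orchestration for the tracing pipeline.

Stages are composable and operate on tidy CSV tables (UTF-8, one
observation per row, a ``#`` header-comment line carrying the schema
version). ``run_pipeline`` chains them: natural-abundance correction ->
mole percent enrichment -> precursor normalization -> CD138+/CD138-
contrasts -> calibration quantitation -> cross-platform concordance,
and writes a run log with the package version, seed and config hash.
Identical config + seed produce byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correction import (
    FragmentSpec,
    IsotopeTable,
    MIDVector,
    build_correction_matrix,
    correct_mid,
    fraction_labeled,
    load_fragment_catalog,
    mole_percent_enrichment,
)
from .enrichment import (
    SampleRecord,
    metabolite_contrast_table,
    normalize_to_precursor,
    subject_ratio_table,
)
from .isotopologue import (
    C5_GLUTAMINE,
    U13C5_GLUTAMINE,
    PathwayModel,
    TracerSpec,
    default_pathway,
)
from .quant import fit_calibration, platform_concordance, quantify

__all__ = [
    "TRACERS",
    "PipelineConfig",
    "read_table",
    "write_table",
    "correct_intensity_table",
    "relative_enrichment_table",
    "estimate_anaplerotic_fractions",
    "quantify_samples",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

TRACERS: dict[str, TracerSpec] = {
    "u13c5": U13C5_GLUTAMINE,
    "5c13": C5_GLUTAMINE,
    U13C5_GLUTAMINE.name: U13C5_GLUTAMINE,
    C5_GLUTAMINE.name: C5_GLUTAMINE,
}


def write_table(df: pd.DataFrame, path, name: str = "table") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# tcatrace {__version__} schema={SCHEMA_VERSION} table={name}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_table(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path}: table has no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _check_numeric(df: pd.DataFrame, column: str, path="table") -> None:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = df.index[values.isna()].tolist()
    if bad:
        raise ValueError(
            f"{path}: non-numeric or missing {column!r} in rows {bad[:10]}"
        )


def correct_intensity_table(
    raw: pd.DataFrame,
    fragments: dict[str, FragmentSpec] | None = None,
    isotopes: IsotopeTable | None = None,
    tracer_purity: float = 0.99,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Natural-abundance-correct a tidy SIM intensity table.

    ``raw`` needs columns sample_id, metabolite, channel (M0..Mn+2),
    intensity, and optionally subject_id/group/fraction which are carried
    through. Returns (corrected MID table, MPE table).
    """
    for col in ("sample_id", "metabolite", "channel", "intensity"):
        if col not in raw.columns:
            raise ValueError(f"raw intensity table missing column {col!r}")
    _check_numeric(raw, "intensity", "raw intensity table")
    fragments = fragments or load_fragment_catalog()
    isotopes = isotopes or IsotopeTable.default()
    carry = [c for c in ("subject_id", "group", "fraction") if c in raw.columns]

    matrices: dict[str, object] = {}
    mid_rows, mpe_rows = [], []
    for (sample, met), chunk in raw.groupby(["sample_id", "metabolite"], sort=True):
        if met not in fragments:
            raise KeyError(f"metabolite {met!r} not in the fragment catalog")
        if met not in matrices:
            matrices[met] = build_correction_matrix(
                fragments[met], isotopes, tracer_purity)
        order = chunk["channel"].str.removeprefix("M").astype(int)
        chunk = chunk.assign(_ch=order).sort_values("_ch")
        values = chunk["intensity"].to_numpy(dtype=float)
        corrected = correct_mid(MIDVector(met, values), matrices[met])
        carried = {c: chunk.iloc[0][c] for c in carry}
        for i, v in enumerate(corrected.values):
            mid_rows.append({
                "sample_id": sample, **carried, "metabolite": met,
                "channel": f"M{i}", "fraction_of_pool": float(v),
            })
        mpe_rows.append({
            "sample_id": sample, **carried, "metabolite": met,
            "mpe": mole_percent_enrichment(corrected),
            "fraction_labeled": fraction_labeled(corrected),
        })
    return pd.DataFrame(mid_rows), pd.DataFrame(mpe_rows)


def relative_enrichment_table(
    mpe: pd.DataFrame, plasma: pd.DataFrame
) -> pd.DataFrame:
    """Normalize per-sample MPE to the subject's plasma glutamine
    enrichment (precursor-product normalization)."""
    for col in ("subject_id", "metabolite", "mpe"):
        if col not in mpe.columns:
            raise ValueError(f"MPE table missing column {col!r}")
    plasma_by_subject = plasma.set_index("subject_id")["enrichment"]
    rows = []
    for (sample, subject, fraction), chunk in mpe.groupby(
        ["sample_id", "subject_id", "fraction"], sort=True
    ):
        if subject not in plasma_by_subject.index:
            raise ValueError(f"no plasma enrichment for subject {subject!r}")
        record = SampleRecord(
            subject_id=subject,
            group=chunk.iloc[0]["group"] if "group" in chunk.columns else "MM",
            fraction=fraction,
            mpe=dict(zip(chunk["metabolite"], chunk["mpe"])),
            plasma_glutamine_enrichment=float(plasma_by_subject[subject]),
        )
        for rel in normalize_to_precursor(record):
            rows.append({
                "sample_id": sample, "subject_id": subject,
                "group": record.group, "fraction": fraction,
                "metabolite": rel.metabolite,
                "relative_enrichment": rel.value,
            })
    return pd.DataFrame(rows)


def estimate_anaplerotic_fractions(
    relative: pd.DataFrame,
    tracer_by_subject: pd.Series,
    pathway: PathwayModel | None = None,
) -> pd.DataFrame:
    """Invert the first-turn forward model per subject.

    Relative enrichment of a metabolite equals f * shift / n under the
    two-pool mixture model, so f_hat = relative * n / shift, with the
    mass shift taken from the subject's tracer.
    """
    pathway = pathway or default_pathway()
    shift_cache: dict[str, dict[str, int]] = {}
    rows = []
    for _, row in relative.iterrows():
        tracer_name = tracer_by_subject[row["subject_id"]]
        if tracer_name not in TRACERS:
            raise KeyError(f"unknown tracer {tracer_name!r}")
        if tracer_name not in shift_cache:
            shift_cache[tracer_name] = pathway.mass_shifts(TRACERS[tracer_name])
        shift = shift_cache[tracer_name][row["metabolite"]]
        n = pathway.carbons[row["metabolite"]]
        rows.append({
            "subject_id": row["subject_id"],
            "group": row.get("group", ""),
            "fraction": row["fraction"],
            "metabolite": row["metabolite"],
            "f_hat": row["relative_enrichment"] * n / shift,
        })
    return pd.DataFrame(rows)


def quantify_samples(
    calibration: pd.DataFrame,
    responses: pd.DataFrame,
    weighting: str = "none",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit per-analyte calibration curves and quantify sample responses.

    Returns (concentration table with a units column, curve summary).
    """
    curves = {}
    curve_rows = []
    for analyte, chunk in calibration.groupby("analyte", sort=True):
        chunk = chunk.sort_values("concentration")
        pts = chunk[["concentration", "response_ratio"]].to_numpy()
        curve = fit_calibration(pts, analyte=analyte, weighting=weighting)
        curves[analyte] = curve
        curve_rows.append({
            "analyte": analyte, "n_points": len(pts),
            "slope": curve.slope, "intercept": curve.intercept,
            "r_squared": curve.r_squared, "weighting": weighting,
        })
    conc_rows = []
    for _, row in responses.iterrows():
        analyte = row["analyte"]
        if analyte not in curves:
            raise KeyError(f"no calibration curve for analyte {analyte!r}")
        conc_rows.append({
            "sample_id": row["sample_id"], "analyte": analyte,
            "platform": "GC-MS",
            "concentration": quantify(curves[analyte],
                                      float(row["response_ratio"])),
            "units": "umol/L",
        })
    return pd.DataFrame(conc_rows), pd.DataFrame(curve_rows)


@dataclass
class PipelineConfig:
    """Paths and options for an end-to-end run."""

    raw_intensities: str
    plasma_enrichment: str
    metadata: str
    out_dir: str
    seed: int = 0
    calibration: str | None = None
    responses: str | None = None
    lc_concentrations: str | None = None
    fragment_catalog: str | None = None
    isotope_table: str | None = None
    atom_maps: str | None = None
    tracer: str | None = None  # fallback when metadata lacks a tracer column
    tracer_purity: float = 0.99
    adjust_pvalues: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def digest(self) -> str:
        canon = yaml.safe_dump(self.__dict__, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every stage on the configured inputs and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pathway = (PathwayModel.from_config(config.atom_maps)
               if config.atom_maps else default_pathway())
    fragments = load_fragment_catalog(config.fragment_catalog)
    isotopes = (IsotopeTable.from_file(config.isotope_table)
                if config.isotope_table else IsotopeTable.default())

    raw = read_table(config.raw_intensities,
                     ("sample_id", "metabolite", "channel", "intensity"))
    plasma = read_table(config.plasma_enrichment, ("subject_id", "enrichment"))
    metadata = read_table(config.metadata, ("subject_id", "group"))

    mids, mpe = correct_intensity_table(
        raw, fragments, isotopes, config.tracer_purity)
    relative = relative_enrichment_table(mpe, plasma)

    if "tracer" in metadata.columns:
        tracer_by_subject = metadata.set_index("subject_id")["tracer"]
    elif config.tracer:
        tracer_by_subject = pd.Series(
            config.tracer, index=metadata["subject_id"].values)
    else:
        raise ValueError("no tracer column in metadata and no --tracer given")
    fractions = estimate_anaplerotic_fractions(
        relative, tracer_by_subject, pathway)

    stats = pd.concat(
        [metabolite_contrast_table(relative, g, adjust=config.adjust_pvalues)
         for g in relative["group"].unique()],
        ignore_index=True,
    )
    ratios = subject_ratio_table(relative)

    results = {
        "corrected_mids": mids,
        "mpe": mpe,
        "relative_enrichment": relative,
        "anaplerotic_fractions": fractions,
        "group_statistics": stats,
        "fractional_ratios": ratios,
    }

    if config.calibration and config.responses:
        calibration = read_table(config.calibration,
                                 ("analyte", "concentration", "response_ratio"))
        responses = read_table(config.responses,
                               ("sample_id", "analyte", "response_ratio"))
        concentrations, curves = quantify_samples(calibration, responses)
        results["concentrations"] = concentrations
        results["calibration_curves"] = curves
        if config.lc_concentrations:
            lc = read_table(config.lc_concentrations,
                            ("sample_id", "analyte", "concentration"))
            lc = lc[lc.get("platform", "LC-MS") == "LC-MS"]
            rows = []
            for analyte in sorted(set(lc["analyte"]) &
                                  set(concentrations["analyte"])):
                res = platform_concordance(concentrations, lc, analyte)
                rows.append({
                    "analyte": analyte, "slope": res.slope,
                    "intercept": res.intercept, "r": res.r, "n": res.n,
                })
            results["platform_concordance"] = pd.DataFrame(rows)

    for name, df in results.items():
        write_table(df, out / f"{name}.csv", name)
    log = {
        "tcatrace_version": __version__,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "n_samples": int(raw["sample_id"].nunique()),
        "tables_written": sorted(results),
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    logger.info("pipeline complete: %d tables -> %s", len(results), out)
    return results
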