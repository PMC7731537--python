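"""Synthetic cohorts with the statistical structure of an in vivo
13C-glutamine tracing study of clonal plasma-cell disorders.

The generator emulates three arms — healthy volunteers infused with
[5-13C]glutamine and MGUS/MM patients infused with [U-13C5]glutamine —
and emits the same tables the analysis pipeline consumes: sample
metadata, raw SIM isotopologue intensities per sorted cell fraction,
plasma tracer enrichments, calibration/response tables and bone-marrow
plasma concentrations, plus a truth table recording every latent
parameter for recovery tests.

Structure emulated (effect sizes are generator defaults chosen to mimic
the study's qualitative patterns, NOT measured values):

* plateau plasma glutamine enrichment ~ U(0.04, 0.10) in volunteers and
  U(0.03, 0.07) in patients;
* per-subject anaplerotic fractional contributions, lognormal between
  subjects (CV 0.4), with the MM CD138+ fraction elevated over CD138-
  by a mean ratio of 1.5 for every metabolite, and MGUS elevated for
  aspartate only (ratio 1.3);
* bone-marrow plasma concentrations linear in marrow plasma-cell
  percentage (BMPC%): glutamate/aspartate rise with tumor burden,
  glutamine falls;
* SIM measurement noise: per-channel multiplicative CV plus additive
  baseline noise proportional to the total ion intensity.

Raw intensities are the idealized first-turn MIDs pushed through the
same natural-abundance convolution the correction module inverts, so at
zero noise the full pipeline recovers the latent parameters exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .correction import FragmentSpec, IsotopeTable, build_correction_matrix, load_fragment_catalog
from .isotopologue import (
    C5_GLUTAMINE,
    U13C5_GLUTAMINE,
    PathwayModel,
    TracerSpec,
    default_pathway,
    ideal_mid,
)

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "generate_enrichment_timecourse",
    "TRACED_METABOLITES",
]

TRACED_METABOLITES = ("glutamate", "citrate", "fumarate", "malate", "aspartate")

# base concentration (umol/L), slope per BMPC%, lognormal noise sigma
DEFAULT_CONCENTRATION_MODEL = {
    "glutamate": (40.0, 0.60, 0.15),
    "aspartate": (8.0, 0.25, 0.20),
    "glutamine": (550.0, -1.80, 0.08),
    "succinate": (4.0, 0.040, 0.20),
    "fumarate": (1.5, 0.015, 0.20),
    "malate": (3.0, 0.030, 0.20),
    "alpha_ketoglutarate": (6.0, 0.020, 0.20),
}

# analytes carried by both platforms for the concordance check
LC_MS_ANALYTES = ("glutamate", "aspartate")

# response-ratio model per analyte: slope (ratio per umol/L), intercept
DEFAULT_RESPONSE_MODEL = {
    analyte: (0.01, 0.001) for analyte in DEFAULT_CONCENTRATION_MODEL
}


@dataclass
class CohortConfig:
    """Study-condition defaults for the synthetic cohort generator.

    ``seed`` is mandatory: all randomness derives from one PRNG stream.
    """

    seed: int
    n_volunteer: int = 7
    n_mgus: int = 11
    n_mm: int = 12
    metabolites: tuple[str, ...] = TRACED_METABOLITES
    # plateau plasma glutamine tracer enrichment per group (uniform range)
    enrichment_range: dict = field(default_factory=lambda: {
        "volunteer": (0.04, 0.10),
        "MGUS": (0.03, 0.07),
        "MM": (0.03, 0.07),
    })
    # anaplerotic fractional contribution of glutamine, CD138- baseline
    base_anaplerotic_mean: float = 0.20
    between_subject_cv: float = 0.40
    within_subject_sigma: float = 0.20  # log-scale, per fraction x metabolite
    # CD138+/CD138- mean effect ratio per group (metabolite overrides)
    effect_ratio: dict = field(default_factory=lambda: {
        "volunteer": {"default": 1.0},
        "MGUS": {"default": 1.0, "aspartate": 1.3},
        "MM": {"default": 1.5},
    })
    # SIM noise model (replicate-injection precision of SIM peak areas)
    additive_sigma: float = 2e-4   # fraction of total ion intensity
    multiplicative_cv: float = 0.01
    total_intensity: float = 1e6
    intensity_cv: float = 0.30
    tracer_purity: float = 0.99
    # marrow plasma-cell percentage per group (uniform range)
    bmpc_range: dict = field(default_factory=lambda: {
        "volunteer": (1.0, 4.0),
        "MGUS": (2.0, 9.0),
        "MM": (15.0, 90.0),
    })
    concentration_model: dict = field(
        default_factory=lambda: dict(DEFAULT_CONCENTRATION_MODEL))
    response_model: dict = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_MODEL))
    cross_platform_sigma: float = 0.06  # log-scale per-platform noise
    calibration_points: int = 12
    calibration_cv: float = 0.02
    missingness: float = 0.0  # per fraction x metabolite dropout probability

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        for lo, hi in self.enrichment_range.values():
            if not (0.0 < lo < hi < 1.0):
                raise ValueError("enrichment ranges must lie in (0, 1)")
        if not 0.0 < self.base_anaplerotic_mean < 1.0:
            raise ValueError("base anaplerotic mean must lie in (0, 1)")

    def ratio(self, group: str, metabolite: str) -> float:
        table = self.effect_ratio[group]
        return float(table.get(metabolite, table["default"]))

    def tracer_for(self, group: str, enrichment: float) -> TracerSpec:
        base = C5_GLUTAMINE if group == "volunteer" else U13C5_GLUTAMINE
        return replace(base, enrichment=enrichment)


def _lognormal_from_mean_cv(rng, mean: float, cv: float, size=None):
    sigma = np.sqrt(np.log(1.0 + cv**2))
    mu = np.log(mean) - 0.5 * sigma**2
    return rng.lognormal(mu, sigma, size=size)


def generate_cohort(
    config: CohortConfig,
    pathway: PathwayModel | None = None,
    fragments: dict[str, FragmentSpec] | None = None,
    isotopes: IsotopeTable | None = None,
) -> dict[str, pd.DataFrame]:
    """Generate one synthetic cohort.

    Returns a dict of tidy DataFrames: ``metadata``, ``raw_intensities``,
    ``plasma_enrichment``, ``concentrations``, ``calibration``,
    ``responses`` and ``truth``.
    """
    rng = np.random.default_rng(config.seed)
    pathway = pathway or default_pathway()
    fragments = fragments or load_fragment_catalog()
    isotopes = isotopes or IsotopeTable.default()

    matrices = {
        met: build_correction_matrix(
            fragments[met], isotopes, config.tracer_purity)
        for met in config.metabolites
    }

    meta_rows, enrich_rows, raw_rows, truth_rows = [], [], [], []
    conc_rows, resp_rows = [], []

    arms = (
        [("volunteer", i) for i in range(config.n_volunteer)]
        + [("MGUS", i) for i in range(config.n_mgus)]
        + [("MM", i) for i in range(config.n_mm)]
    )
    for group, idx in arms:
        subject = f"{group}_{idx + 1:02d}"
        lo, hi = config.enrichment_range[group]
        e = float(rng.uniform(lo, hi))
        blo, bhi = config.bmpc_range[group]
        bmpc = float(rng.uniform(blo, bhi))
        tracer = config.tracer_for(group, e)
        shifts = pathway.mass_shifts(tracer)

        meta_rows.append({
            "subject_id": subject, "group": group,
            "tracer": tracer.name, "bmpc_percent": bmpc,
        })
        enrich_rows.append({
            "subject_id": subject, "compartment": "BM plasma",
            "tracer": tracer.name, "enrichment": e,
        })

        f_base = float(_lognormal_from_mean_cv(
            rng, config.base_anaplerotic_mean, config.between_subject_cv))
        for fraction in ("CD138+", "CD138-"):
            sample_id = f"{subject}_{'pos' if fraction == 'CD138+' else 'neg'}"
            for met in config.metabolites:
                if config.missingness > 0 and rng.uniform() < config.missingness:
                    continue
                ratio = config.ratio(group, met) if fraction == "CD138+" else 1.0
                f = f_base * ratio * float(
                    rng.lognormal(0.0, config.within_subject_sigma))
                f = float(np.clip(f, 1e-4, 0.95))
                x = ideal_mid(tracer, met, f, pathway)
                raw_frac = matrices[met].matrix @ x
                total = config.total_intensity * float(
                    rng.lognormal(0.0, config.intensity_cv))
                noisy = (
                    total * raw_frac
                    * np.exp(rng.normal(0.0, config.multiplicative_cv,
                                        size=raw_frac.shape))
                    + rng.normal(0.0, config.additive_sigma * total,
                                 size=raw_frac.shape)
                )
                noisy = np.clip(noisy, 0.0, None)
                for ch, val in enumerate(noisy):
                    raw_rows.append({
                        "sample_id": sample_id, "subject_id": subject,
                        "group": group, "fraction": fraction,
                        "metabolite": met, "channel": f"M{ch}",
                        "intensity": float(val),
                    })
                truth_rows.append({
                    "subject_id": subject, "group": group,
                    "fraction": fraction, "metabolite": met,
                    "f_true": f, "enrichment": e, "bmpc_percent": bmpc,
                    "mass_shift": shifts[met],
                    "n_carbons": pathway.carbons[met],
                })

        # bone-marrow plasma concentrations, both platforms
        for analyte, (base, slope, sigma) in config.concentration_model.items():
            true_c = max(base + slope * bmpc, 0.01)
            gc_c = true_c * float(rng.lognormal(0.0, config.cross_platform_sigma))
            r_slope, r_int = config.response_model[analyte]
            resp_rows.append({
                "sample_id": subject, "analyte": analyte,
                "response_ratio": r_slope * gc_c + r_int,
            })
            conc_rows.append({
                "sample_id": subject, "group": group, "analyte": analyte,
                "platform": "GC-MS", "concentration": gc_c,
                "units": "umol/L",
            })
            if analyte in LC_MS_ANALYTES:
                lc_c = true_c * float(
                    rng.lognormal(0.0, config.cross_platform_sigma))
                conc_rows.append({
                    "sample_id": subject, "group": group, "analyte": analyte,
                    "platform": "LC-MS", "concentration": lc_c,
                    "units": "umol/L",
                })

    # calibration curves, one per analyte, sharing the cohort PRNG stream
    cal_rows = []
    for analyte, (r_slope, r_int) in config.response_model.items():
        base, slope, _ = config.concentration_model[analyte]
        top = 2.0 * (base + max(slope, 0.0) * 100.0)
        concs = np.linspace(top / config.calibration_points, top,
                            config.calibration_points)
        for level, c in enumerate(concs, start=1):
            resp = (r_slope * c + r_int) * float(
                rng.lognormal(0.0, config.calibration_cv))
            cal_rows.append({
                "analyte": analyte, "level": level,
                "concentration": float(c), "response_ratio": resp,
                "units": "umol/L",
            })

    return {
        "metadata": pd.DataFrame(meta_rows),
        "raw_intensities": pd.DataFrame(raw_rows),
        "plasma_enrichment": pd.DataFrame(enrich_rows),
        "concentrations": pd.DataFrame(conc_rows),
        "calibration": pd.DataFrame(cal_rows),
        "responses": pd.DataFrame(resp_rows),
        "truth": pd.DataFrame(truth_rows),
    }


def generate_enrichment_timecourse(
    plateau: float,
    n_timepoints: int = 5,
    jitter_cv: float = 0.02,
    duration_min: float = 60.0,
    rise_tau_min: float = 4.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Plasma tracer enrichment during a bolus + continuous infusion.

    Rapid rise to the subject's plateau within the first sampling
    interval (~15 min), then flat with small jitter. Returns a frame
    with columns ``time_min`` and ``enrichment``.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    if not 0.0 < plateau < 1.0:
        raise ValueError("plateau enrichment must lie in (0, 1)")
    rng = rng or np.random.default_rng(0)
    t = np.linspace(0.0, duration_min, n_timepoints)
    e = plateau * (1.0 - np.exp(-t / rise_tau_min))
    if jitter_cv > 0:
        e = e * np.exp(rng.normal(0.0, jitter_cv, size=e.shape))
    e[0] = 0.0
    return pd.DataFrame({"time_min": t, "enrichment": e})
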