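"""Synthetic multi-cohort case-control data with a known effect structure.

The generator draws subject-level data from the model that the one-stage
mixed-effects analysis assumes:

    y_ij = grand_mean + u_i + (beta_dx + b_i) * dx_ij + covariate terms + e_ij

with cohort intercepts u_i ~ N(0, sigma_u^2), cohort-specific deviations of
the diagnosis effect b_i ~ N(0, sigma_slope^2) and residuals
e_ij ~ N(0, sigma_e_i^2), optionally heteroscedastic across cohorts.
Setting sigma_slope = 0 with a common sigma_e reproduces the classical
regime in which two-stage pooling and one-stage regression are equivalent
(constant effects and error variances across studies).

``default_enigma_structure`` packages a 38-cohort configuration whose
patient/control and pediatric/adult totals match the published composition
of a large multi-site OCD sample (3,665 subjects) with 70 cortical outcome
measures registered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import IPDDataset


class ConfigError(ValueError):
    """Invalid scenario configuration."""


@dataclass(frozen=True)
class AgeModel:
    """Pediatric/adult mixture: proportions and uniform age ranges.

    ``p_pediatric`` is a scalar applied to every cohort or a per-cohort
    sequence; the pediatric count within each cohort x diagnosis cell is
    ``round(p * n)``, so proportions of 0 and 1 yield exact single-stratum
    cohorts.  Ages are uniform within the pediatric and adult ranges.
    """

    p_pediatric: float | tuple[float, ...] = 0.0
    pediatric_range: tuple[float, float] = (8.0, 18.0)
    adult_range: tuple[float, float] = (18.0, 65.0)

    def proportion(self, i: int) -> float:
        if isinstance(self.p_pediatric, (int, float)):
            return float(self.p_pediatric)
        return float(self.p_pediatric[i])


def _default_covariate_effects() -> dict[str, float]:
    return {"age": 0.0, "sex": 0.0, "icv": 0.0}


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator parameters for one simulation scenario.

    Parameters
    ----------
    cohort_sizes
        ``(n_patients, n_controls)`` per cohort; length defines K.
    beta_dx
        True diagnosis effect in outcome units (negative = lower in patients).
    sigma_u, sigma_slope
        SDs of the cohort random intercept and of cohort-specific deviations
        of the diagnosis effect, in outcome units.
    sigma_e
        Residual SD, a scalar (homoscedastic) or one value per cohort.
    covariate_effects
        Linear coefficients for age (per year), sex (0/1) and icv (per mm^3).
    grand_mean
        Outcome intercept for a control at covariate value zero.
    roi_registry
        ROI outcome columns to generate; all share the same effect structure
        (common cohort effects, independent residual draws per ROI).
    """

    cohort_sizes: tuple[tuple[int, int], ...]
    beta_dx: float = 0.0
    sigma_u: float = 0.0
    sigma_slope: float = 0.0
    sigma_e: float | tuple[float, ...] = 1.0
    covariate_effects: Mapping[str, float] = field(
        default_factory=_default_covariate_effects
    )
    age_model: AgeModel = field(default_factory=AgeModel)
    grand_mean: float = 0.0
    roi_registry: tuple[tuple[str, str], ...] = (("roi", "thickness"),)
    icv_mean: float = 1.5e6
    icv_sd: float = 1.5e5
    age_split: float = 18.0
    seed: int = 0

    @property
    def n_cohorts(self) -> int:
        return len(self.cohort_sizes)

    def sigma_e_for(self, i: int) -> float:
        if isinstance(self.sigma_e, (int, float)):
            return float(self.sigma_e)
        return float(self.sigma_e[i])

    @property
    def sigma_e_rms(self) -> float:
        """Root-mean-square residual SD across cohorts."""
        vals = [self.sigma_e_for(i) for i in range(self.n_cohorts)]
        return float(np.sqrt(np.mean(np.square(vals))))

    @property
    def true_d(self) -> float:
        """True standardized diagnosis effect, beta_dx / residual SD.

        Uses the RMS residual SD under heteroscedasticity; with sigma_slope
        > 0 this is the standardized effect averaged over cohorts.
        """
        return self.beta_dx / self.sigma_e_rms

    def validate(self) -> None:
        if self.n_cohorts < 1:
            raise ConfigError("need at least one cohort")
        for i, (n1, n2) in enumerate(self.cohort_sizes):
            if n1 < 0 or n2 < 0 or n1 + n2 < 2:
                raise ConfigError(f"cohort {i}: invalid sizes ({n1}, {n2})")
        if self.sigma_u < 0 or self.sigma_slope < 0:
            raise ConfigError("SDs must be nonnegative")
        if not isinstance(self.sigma_e, (int, float)):
            if len(self.sigma_e) != self.n_cohorts:
                raise ConfigError("per-cohort sigma_e length must equal K")
        for i in range(self.n_cohorts):
            if self.sigma_e_for(i) < 0:
                raise ConfigError("sigma_e must be nonnegative")

    def with_(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


def generate_cohorts(
    cfg: ScenarioConfig, seed: int | None = None
) -> IPDDataset:
    """Draw one dataset from the scenario; deterministic given the seed.

    Each cohort consumes an independent substream spawned from the root
    seed, so adding cohorts to a configuration does not perturb the data of
    earlier cohorts.  The realized cohort effects are exposed on the
    returned dataset as ``ds.truth`` (columns ``cohort, u, b, sigma_e``)
    so that tests can verify the generating structure directly.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    streams = root.spawn(cfg.n_cohorts)
    ce = {**_default_covariate_effects(), **dict(cfg.covariate_effects)}
    roi_names = [name for name, _ in cfg.roi_registry]

    frames = []
    truth_rows = []
    width = max(2, len(str(cfg.n_cohorts)))
    for i, (n1, n2) in enumerate(cfg.cohort_sizes):
        rng = np.random.default_rng(streams[i])
        n = n1 + n2
        u_i = rng.normal(0.0, cfg.sigma_u)
        b_i = rng.normal(0.0, cfg.sigma_slope)
        sig_e = cfg.sigma_e_for(i)
        dx = np.concatenate([np.ones(n1, dtype=int), np.zeros(n2, dtype=int)])

        p_ped = cfg.age_model.proportion(i)
        ages = np.empty(n)
        pos = 0
        for grp_n in (n1, n2):
            n_ped = int(round(p_ped * grp_n))
            lo, hi = cfg.age_model.pediatric_range
            ages[pos : pos + n_ped] = rng.uniform(lo, hi, n_ped)
            lo, hi = cfg.age_model.adult_range
            ages[pos + n_ped : pos + grp_n] = rng.uniform(lo, hi, grp_n - n_ped)
            pos += grp_n
        sex = rng.integers(0, 2, n)
        icv = rng.normal(cfg.icv_mean, cfg.icv_sd, n)
        while (icv <= 0).any():  # truncate at zero; essentially never triggers
            icv[icv <= 0] = rng.normal(cfg.icv_mean, cfg.icv_sd, int((icv <= 0).sum()))

        mean = (
            cfg.grand_mean
            + u_i
            + (cfg.beta_dx + b_i) * dx
            + ce["age"] * ages
            + ce["sex"] * sex
            + ce["icv"] * icv
        )
        cohort_id = f"cohort_{i + 1:0{width}d}"
        cols = {
            "cohort": cohort_id,
            "dx": dx,
            "age": ages,
            "sex": sex,
            "icv": icv,
        }
        for roi in roi_names:
            cols[roi] = mean + rng.normal(0.0, sig_e, n)
        frames.append(pd.DataFrame(cols))
        truth_rows.append(
            {"cohort": cohort_id, "u": u_i, "b": b_i, "sigma_e": sig_e}
        )

    df = pd.concat(frames, ignore_index=True)
    ds = IPDDataset(df, list(cfg.roi_registry), age_split=cfg.age_split)
    ds.truth = pd.DataFrame(truth_rows)  # type: ignore[attr-defined]
    return ds


# ---------------------------------------------------------------------------
# packaged multi-site structure
# ---------------------------------------------------------------------------

# Desikan-Killiany cortical parcels (34 per hemisphere) plus a mean-thickness
# measure per hemisphere: 70 outcome columns.
_DK_REGIONS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
)

# Printed composition of the multi-site OCD sample the default structure
# emulates: 38 cohorts, 3,665 subjects in four strata.
ENIGMA_TOTALS = {
    "pediatric_patients": 407,
    "pediatric_controls": 324,
    "adult_patients": 1498,
    "adult_controls": 1436,
}
N_PEDIATRIC_COHORTS = 10
N_ADULT_COHORTS = 28


def dk_roi_registry(measure_type: str = "thickness") -> tuple[tuple[str, str], ...]:
    """68 left/right cortical parcels + 2 hemisphere means (70 measures)."""
    names = [f"L_{r}" for r in _DK_REGIONS] + [f"R_{r}" for r in _DK_REGIONS]
    names += ["L_hemisphere_mean", "R_hemisphere_mean"]
    return tuple((n, measure_type) for n in names)


def _spread(total: int, k: int) -> list[int]:
    """Even integer split of ``total`` over ``k`` cells, remainder to the first."""
    base, rem = divmod(total, k)
    return [base + (1 if j < rem else 0) for j in range(k)]


def default_enigma_structure(seed: int = 0, n_rois: int | None = None) -> ScenarioConfig:
    """38-cohort configuration matching the published sample composition.

    The four strata (pediatric/adult x patient/control) are spread over 10
    pediatric-only and 28 adult-only cohorts by even integer division, the
    only constraint the printed totals impose.  Outcome defaults emulate
    cortical thickness in mm: grand mean 2.5, residual SD 0.15, cohort
    intercept SD 0.05 (moderate site variation), diagnosis effect -0.02 mm
    (standardized effect about -0.13, the order of magnitude reported for
    adult case-control cortical differences), age slope -0.005 mm/year,
    sex difference 0.01 mm.

    ``n_rois`` optionally truncates the 70-measure registry (simulation
    studies typically need a single outcome).
    """
    ped_pat = _spread(ENIGMA_TOTALS["pediatric_patients"], N_PEDIATRIC_COHORTS)
    ped_con = _spread(ENIGMA_TOTALS["pediatric_controls"], N_PEDIATRIC_COHORTS)
    adu_pat = _spread(ENIGMA_TOTALS["adult_patients"], N_ADULT_COHORTS)
    adu_con = _spread(ENIGMA_TOTALS["adult_controls"], N_ADULT_COHORTS)
    sizes = tuple(zip(ped_pat, ped_con)) + tuple(zip(adu_pat, adu_con))
    p_ped = tuple([1.0] * N_PEDIATRIC_COHORTS + [0.0] * N_ADULT_COHORTS)
    registry = dk_roi_registry("thickness")
    if n_rois is not None:
        registry = registry[:n_rois]
    return ScenarioConfig(
        cohort_sizes=sizes,
        beta_dx=-0.02,
        sigma_u=0.05,
        sigma_slope=0.0,
        sigma_e=0.15,
        covariate_effects={"age": -0.005, "sex": 0.01, "icv": 0.0},
        age_model=AgeModel(p_pediatric=p_ped),
        grand_mean=2.5,
        roi_registry=registry,
        seed=seed,
    )
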