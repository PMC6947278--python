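"""Simulated per-eye metric cohorts.

Group-level summary distributions (mean ± SD per group, region, metric and
visit) parameterize a per-eye sampler: each eye's values across visits are
drawn from a Gaussian copula with equicorrelation rho (normal marginals at
the cell means/SDs), producing the long-format table the statistics stage
consumes.  The default parameter map carries the published baseline
distributions of the four SCP metrics in both macular regions for the
epiretinal-membrane (iERM) and control groups, and the three-visit central
macular thickness / visual-acuity trajectories of the surgical group.

Note the control vessel-tortuosity location 0.7 is kept exactly as
published even though an arc/chord ratio below 1 is not producible by the
measurement pipeline: in simulation it acts purely as a location parameter
separating the groups.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

VISITS = ("baseline", "1mo", "6mo")

#: (group, region, metric) -> {visit: (mean, sd)}.  OCTA metrics have
#: published distributions at baseline; CMT and BCVA across all visits for
#: the iERM group.
DEFAULT_GROUP_PARAMS: dict[tuple[str, str, str], dict[str, tuple[float, float]]] = {
    ("iERM", "parafoveal", "PD"): {"baseline": (25.3, 1.8)},
    ("control", "parafoveal", "PD"): {"baseline": (30.6, 4.4)},
    ("iERM", "parafoveal", "VLD"): {"baseline": (6.8, 0.7)},
    ("control", "parafoveal", "VLD"): {"baseline": (8.8, 1.3)},
    ("iERM", "parafoveal", "VDI"): {"baseline": (18.5, 1.9)},
    ("control", "parafoveal", "VDI"): {"baseline": (21.7, 3.2)},
    ("iERM", "parafoveal", "VT"): {"baseline": (1.4, 0.1)},
    ("control", "parafoveal", "VT"): {"baseline": (0.7, 0.1)},
    ("iERM", "perifoveal", "PD"): {"baseline": (39.4, 3.6)},
    ("control", "perifoveal", "PD"): {"baseline": (42.3, 1.8)},
    ("iERM", "perifoveal", "VLD"): {"baseline": (10.2, 1.6)},
    ("control", "perifoveal", "VLD"): {"baseline": (11.3, 0.7)},
    ("iERM", "perifoveal", "VDI"): {"baseline": (29.1, 2.3)},
    ("control", "perifoveal", "VDI"): {"baseline": (31.0, 1.3)},
    ("iERM", "perifoveal", "VT"): {"baseline": (1.4, 0.1)},
    ("control", "perifoveal", "VT"): {"baseline": (0.7, 0.1)},
    ("iERM", "macular", "CMT"): {"baseline": (512.3, 23.4),
                                 "1mo": (374.5, 31.7),
                                 "6mo": (374.0, 49.3)},
    ("control", "macular", "CMT"): {"baseline": (185.9, 12.9)},
    ("iERM", "macular", "BCVA"): {"baseline": (0.78, 0.38),
                                  "1mo": (0.53, 0.34),
                                  "6mo": (0.32, 0.40)},
    ("control", "macular", "BCVA"): {"baseline": (0.10, 0.41)},
}

#: published gender counts (male, female) per group, used by the
#: demographics chi-square in the study replica
DEFAULT_GENDER_COUNTS = {"iERM": (8, 16), "control": (10, 14)}


class CohortConfigError(ValueError):
    """Raised when a requested distribution cell is missing or invalid."""


@dataclasses.dataclass
class CohortSpec:
    """Sampler configuration for one simulated study.

    ``within_eye_corr`` is the cross-visit correlation of one eye's values
    (the study reports none; 0.5 is a free simulator knob).
    ``interobserver_corr`` is used when ``n_graders=2`` to draw paired
    grader readings (no bias), emulating the published interobserver
    concordance of 0.99.
    """

    n_per_group: int = 24
    group_params: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS))
    within_eye_corr: float = 0.5
    interobserver_corr: float = 0.995
    n_graders: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise CohortConfigError("n_per_group must be >= 2")
        if not 0.0 <= self.within_eye_corr < 1.0:
            raise CohortConfigError("within_eye_corr must lie in [0, 1)")
        for cell, visits in self.group_params.items():
            for visit, (mean, sd) in visits.items():
                if not sd > 0:
                    raise CohortConfigError(f"SD must be > 0 in cell {cell}/{visit}")


def _equicorr_cholesky(k: int, rho: float) -> np.ndarray:
    cov = np.full((k, k), rho)
    np.fill_diagonal(cov, 1.0)
    return np.linalg.cholesky(cov)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw the long-format cohort table.

    One row per eye x region x metric x visit (x grader when two graders
    are simulated); columns ``eye_id, group, region, metric, visit, value,
    grader``.  Deterministic for a fixed spec + seed; sample moments of each
    cell converge to the specified mean/SD as n grows.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    for (group, region, metric), visit_params in sorted(spec.group_params.items()):
        visits = [v for v in VISITS if v in visit_params]
        if not visits:
            raise CohortConfigError(
                f"no visit distributions for cell {(group, region, metric)}")
        L = _equicorr_cholesky(len(visits), spec.within_eye_corr)
        for i in range(spec.n_per_group):
            eye = f"{group}-{i + 1:03d}"
            z = L @ rng.standard_normal(len(visits))
            for zv, visit in zip(z, visits):
                mean, sd = visit_params[visit]
                base_value = mean + sd * zv
                if spec.n_graders == 1:
                    rows.append(dict(eye_id=eye, group=group, region=region,
                                     metric=metric, visit=visit,
                                     value=base_value, grader="G1"))
                else:
                    r = spec.interobserver_corr
                    # paired readings around the same latent eye value
                    z2 = r * zv + np.sqrt(1 - r**2) * rng.standard_normal()
                    for grader, zz in (("G1", zv), ("G2", z2)):
                        rows.append(dict(eye_id=eye, group=group, region=region,
                                         metric=metric, visit=visit,
                                         value=mean + sd * zz, grader=grader))
    return pd.DataFrame(rows)


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"eye_id", "group", "region", "metric", "visit", "value"}
    missing = required - set(df.columns)
    if missing:
        raise CohortConfigError(f"cohort table missing columns: {sorted(missing)}")
    return df
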