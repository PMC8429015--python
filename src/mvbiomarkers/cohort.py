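"""Synthetic two-view, four-group cohorts.

Generates cohorts with the statistical structure the subspace-learning
method assumes: AD and NC occupy opposite class means along a small set
of informative features, while pMCI sits near AD and sMCI near NC. Each
subject carries a latent signal partially shared between the thickness
and volume views, so that the two views agree on class identity to a
controllable degree.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

GROUPS = ("AD", "NC", "pMCI", "sMCI")


class CohortSpecError(ValueError):
    """Raised when a CohortSpec violates its invariants."""


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-view cohort.

    Parameters
    ----------
    n_per_group
        Subject counts for each of ``AD``, ``NC``, ``pMCI``, ``sMCI``.
        Missing groups default to zero.
    d
        Number of region features per view (default 78, matching the
        AAL cortical parcellation after removal of subcortical regions).
    delta
        Between-class (AD vs NC) mean separation on each informative
        feature, in units of within-class standard deviation.
    rho
        Cross-view coupling in [0, 1]: the fraction of a subject's
        latent signal shared between the two views.
    noise_sd
        Standard deviation of per-feature measurement noise (> 0).
    n_informative
        Number of leading features carrying class signal.
    mix
        How far the pMCI mean sits from the AD mean toward the NC mean
        (and symmetrically sMCI from NC toward AD), in [0, 0.5].
    baseline
        Positive offset added to every feature, emulating raw
        morphometric measurements (regional thickness and volume are
        large and positive, with disease shifting them by a fraction of
        their magnitude). Class effects are deviations around it.
    seed
        Seed for the cohort's private random generator.
    """

    n_per_group: Mapping[str, int]
    d: int = 78
    delta: float = 1.0
    rho: float = 0.5
    noise_sd: float = 1.0
    n_informative: int = 10
    mix: float = 0.25
    baseline: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_per_group) - set(GROUPS)
        if unknown:
            raise CohortSpecError(f"n_per_group has unknown groups: {sorted(unknown)}")
        for g, n in self.n_per_group.items():
            if not (isinstance(n, (int, np.integer)) and n >= 0):
                raise CohortSpecError(f"n_per_group[{g!r}] must be a nonnegative integer, got {n!r}")
        if self.d < 1:
            raise CohortSpecError(f"d must be >= 1, got {self.d}")
        if not self.noise_sd > 0:
            raise CohortSpecError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0.0 <= self.rho <= 1.0:
            raise CohortSpecError(f"rho must be in [0, 1], got {self.rho}")
        if not 0.0 <= self.mix <= 0.5:
            raise CohortSpecError(f"mix must be in [0, 0.5], got {self.mix}")
        if not 1 <= self.n_informative <= self.d:
            raise CohortSpecError(
                f"n_informative must be in [1, d={self.d}], got {self.n_informative}"
            )

    def count(self, group: str) -> int:
        return int(self.n_per_group.get(group, 0))

    @property
    def n_total(self) -> int:
        return sum(self.count(g) for g in GROUPS)

    def group_mean(self, group: str) -> np.ndarray:
        """Population mean feature vector of one group (length d)."""
        dev_ad = np.zeros(self.d)
        dev_ad[: self.n_informative] = +self.delta / 2.0
        dev_nc = -dev_ad
        base = np.full(self.d, self.baseline)
        if group == "AD":
            return base + dev_ad
        if group == "NC":
            return base + dev_nc
        if group == "pMCI":
            return base + (1.0 - self.mix) * dev_ad + self.mix * dev_nc
        if group == "sMCI":
            return base + (1.0 - self.mix) * dev_nc + self.mix * dev_ad
        raise CohortSpecError(f"unknown group {group!r}")


@dataclasses.dataclass
class SyntheticCohort:
    """A generated cohort: two aligned d x N feature blocks plus labels."""

    X_CT: np.ndarray
    X_CV: np.ndarray
    group_labels: np.ndarray
    spec: CohortSpec

    @property
    def n(self) -> int:
        return self.X_CT.shape[1]

    def subject_ids(self) -> list[str]:
        width = max(4, len(str(self.n)))
        return [f"sub-{i + 1:0{width}d}" for i in range(self.n)]

    def subset(self, mask: np.ndarray) -> "SyntheticCohort":
        """Column subset by boolean mask or index array (labels kept aligned)."""
        return SyntheticCohort(
            X_CT=self.X_CT[:, mask],
            X_CV=self.X_CV[:, mask],
            group_labels=self.group_labels[mask],
            spec=self.spec,
        )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort from the two-view latent-signal model.

    Each subject's signal in a view is ``mu_g + (rho*e_shared +
    (1-rho)*e_private) / sqrt(rho^2 + (1-rho)^2)``, where the ``e`` are
    independent standard-normal draws; the normalization keeps the
    within-class signal spread at exactly unit standard deviation for
    every coupling ``rho``. Independent Gaussian noise with standard
    deviation ``noise_sd`` is added per view. Only the first
    ``n_informative`` coordinates carry class-mean differences.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    d, N = spec.d, spec.n_total

    mu = np.zeros((d, N))
    labels = np.empty(N, dtype=object)
    pos = 0
    for g in GROUPS:
        n_g = spec.count(g)
        if n_g == 0:
            continue
        mu[:, pos : pos + n_g] = spec.group_mean(g)[:, None]
        labels[pos : pos + n_g] = g
        pos += n_g

    scale = float(np.hypot(spec.rho, 1.0 - spec.rho))
    e_shared = rng.standard_normal((d, N))
    e_ct = rng.standard_normal((d, N))
    e_cv = rng.standard_normal((d, N))
    noise_ct = rng.standard_normal((d, N)) * spec.noise_sd
    noise_cv = rng.standard_normal((d, N)) * spec.noise_sd

    w_sh, w_pr = spec.rho / scale, (1.0 - spec.rho) / scale
    X_CT = mu + w_sh * e_shared + w_pr * e_ct + noise_ct
    X_CV = mu + w_sh * e_shared + w_pr * e_cv + noise_cv

    return SyntheticCohort(X_CT=X_CT, X_CV=X_CV, group_labels=labels.astype(str), spec=spec)


def region_names(d: int) -> list[str]:
    return [f"region_{i + 1:03d}" for i in range(d)]


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path, prefix: str = "cohort") -> dict[str, Path]:
    """Write the cohort as CSV tables (rows = subjects, columns = regions).

    Produces ``<prefix>_ct.csv``, ``<prefix>_cv.csv`` and
    ``<prefix>_labels.csv`` under ``out_dir``; returns the paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = cohort.subject_ids()
    cols = region_names(cohort.spec.d)
    paths = {}
    for tag, X in (("ct", cohort.X_CT), ("cv", cohort.X_CV)):
        df = pd.DataFrame(X.T, columns=cols)
        df.insert(0, "subject_id", ids)
        path = out_dir / f"{prefix}_{tag}.csv"
        df.to_csv(path, index=False, float_format="%.17g")
        paths[tag] = path
    lab = pd.DataFrame({"subject_id": ids, "group": cohort.group_labels})
    paths["labels"] = out_dir / f"{prefix}_labels.csv"
    lab.to_csv(paths["labels"], index=False)
    return paths
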