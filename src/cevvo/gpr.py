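"""Gaussian-process synthesis of ECMO cohorts with a tunable dependency range.

Patients are grouped by outcome into run-length-sorted triplets; for each
triplet one GP regressor per perfusion variable (8 in total) is fitted on the
stacked member data, with covariates (standardized age, numeric sex code,
standardized BMI, raw time-step index) and the *unnormalized* perfusion values
as targets.  The kernel is ``k(x_i, x_j) = exp(-d(x_i, x_j)^2 / (2 L))`` with
``d`` the Euclidean distance — note the ``2L`` denominator; the conventional
``2L^2`` form is available via ``convention="squared"``.  The length scale
``L`` controls how far temporal dependencies reach: posterior samples at small
``L`` retain the fast local structure of the source runs, at large ``L`` they
are smoothed.  Sampling the fitted posteriors yields synthetic cohorts used to
test whether temporal dependence drives classifier performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve, cholesky
from scipy.spatial.distance import cdist

from .cohort import PatientRecord, standardize_length

__all__ = [
    "rbf_kernel", "rbf_kernel_matrix",
    "Triplet", "TripletGPR", "SyntheticFoldPlan",
    "form_triplets", "fit_triplet_gprs",
    "sample_synthetic_cohort", "split_synthetic_folds",
]


def _scale(L: float, convention: str) -> float:
    if L <= 0:
        raise ValueError(f"length scale L must be positive, got {L}")
    if convention == "as_printed":
        return 2.0 * L
    if convention == "squared":
        return 2.0 * L * L
    raise ValueError(f"unknown kernel convention {convention!r}")


def rbf_kernel(xi, xj, L: float, convention: str = "as_printed") -> float:
    """RBF kernel value between two covariate vectors.

    ``exp(-||xi - xj||^2 / (2 L))`` under the default convention, or with a
    ``2 L^2`` denominator under ``convention="squared"``.
    """
    xi = np.asarray(xi, dtype=float).ravel()
    xj = np.asarray(xj, dtype=float).ravel()
    d2 = float(np.sum((xi - xj) ** 2))
    return float(np.exp(-d2 / _scale(L, convention)))


def rbf_kernel_matrix(Xa, Xb, L: float, convention: str = "as_printed") -> np.ndarray:
    """Pairwise RBF kernel matrix between covariate rows of ``Xa`` and ``Xb``."""
    d2 = cdist(np.atleast_2d(Xa), np.atleast_2d(Xb), metric="sqeuclidean")
    return np.exp(-d2 / _scale(L, convention))


@dataclass
class Triplet:
    """Three same-outcome patients with adjacent run lengths, stacked for GP fitting."""

    triplet_id: str
    member_ids: tuple                 # 3 patient ids, run-length order
    outcome: int
    covariate_matrix: np.ndarray      # (3T, 4): age_z, sex_z, bmi_z, time step
    targets: np.ndarray               # (3T, 8): unnormalized perfusion values
    member_statics: tuple             # per member: the standardized (age, sex, bmi)
    member_records: tuple             # the source PatientRecords
    grid_length: int
    channels: tuple


@dataclass
class _VariableGP:
    """One fitted GP posterior for a single perfusion variable."""

    channel: str
    jitter: float
    chol: tuple = field(repr=False, default=None)   # cho_factor of K + jitter*I
    alpha: np.ndarray = field(repr=False, default=None)


@dataclass
class TripletGPR:
    """Per-triplet bundle of 8 fitted GP regressors sharing covariates and kernel."""

    triplet: Triplet
    length_scale: float
    convention: str
    regressors: list                  # 8 _VariableGP, one per channel

    def posterior_mean(self, Xstar: np.ndarray) -> np.ndarray:
        """Posterior means at covariates ``Xstar`` -> (len(Xstar), 8)."""
        Ks = rbf_kernel_matrix(self.triplet.covariate_matrix, Xstar,
                               self.length_scale, self.convention)
        return np.column_stack([Ks.T @ gp.alpha for gp in self.regressors])

    def _member_grid(self, member_idx: int) -> np.ndarray:
        T = self.triplet.grid_length
        age_z, sex_z, bmi_z = self.triplet.member_statics[member_idx]
        X = np.empty((T, 4))
        X[:, 0], X[:, 1], X[:, 2] = age_z, sex_z, bmi_z
        X[:, 3] = np.arange(T)
        return X

    def sample(self, member_idx: int, n_draws: int, rng: np.random.Generator,
               ) -> np.ndarray:
        """Joint posterior draws over the full time grid -> (n_draws, T, 8)."""
        X = self.triplet.covariate_matrix
        Xstar = self._member_grid(member_idx)
        Ks = rbf_kernel_matrix(X, Xstar, self.length_scale, self.convention)
        Kss = rbf_kernel_matrix(Xstar, Xstar, self.length_scale, self.convention)
        T = Xstar.shape[0]
        out = np.empty((n_draws, T, len(self.regressors)))
        for v, gp in enumerate(self.regressors):
            mean = Ks.T @ gp.alpha
            cov = Kss - Ks.T @ cho_solve(gp.chol, Ks)
            cov[np.diag_indices_from(cov)] += gp.jitter
            try:
                Lc = cholesky(cov, lower=True)
            except LinAlgError:
                # clip tiny negative eigenvalues from floating-point cancellation
                w, V = np.linalg.eigh(cov)
                Lc = V * np.sqrt(np.clip(w, 0.0, None))
            z = rng.standard_normal((T, n_draws))
            out[:, :, v] = (mean[:, None] + Lc @ z).T
        return out


def form_triplets(records: list[PatientRecord], grid_length: int = 2054,
                  sex_levels: tuple = ("female", "male")) -> list[Triplet]:
    """Group patients into same-outcome, run-length-sorted, non-overlapping triplets.

    Within each outcome group patients are sorted by ECMO run time and taken as
    consecutive triples; the remainder (group size mod 3) is dropped with a
    warning.  Age, sex (coded 0/1) and BMI are standardized to zero mean / unit
    variance over all input records; the time covariate is the raw grid index.
    Targets are each member's raw series stretched onto the grid, unnormalized.
    """
    stat = np.array([[r.age, float(sex_levels.index(r.sex)), r.bmi]
                     for r in records], dtype=float)
    mu = stat.mean(axis=0)
    sd = stat.std(axis=0)
    sd[sd == 0] = 1.0
    zstat = {r.patient_id: (stat[i] - mu) / sd for i, r in enumerate(records)}

    triplets = []
    for outcome, tag in ((1, "S"), (0, "U")):
        group = sorted((r for r in records if r.outcome == outcome),
                       key=lambda r: r.run_seconds)
        n_keep = 3 * (len(group) // 3)
        if len(group) < 3:
            warnings.warn(f"outcome-{outcome} group has {len(group)} patients; "
                          "no triplets formed", stacklevel=2)
        elif n_keep < len(group):
            warnings.warn(f"outcome-{outcome} group: {len(group) - n_keep} "
                          "patient(s) dropped to form whole triplets", stacklevel=2)
        for idx in range(n_keep // 3):
            members = group[3 * idx: 3 * idx + 3]
            cov_rows, target_rows, statics = [], [], []
            for m in members:
                z = zstat[m.patient_id]
                X = np.empty((grid_length, 4))
                X[:, :3] = z
                X[:, 3] = np.arange(grid_length)
                cov_rows.append(X)
                target_rows.append(standardize_length(m.perfusion, grid_length))
                statics.append(tuple(z))
            triplets.append(Triplet(
                triplet_id=f"{tag}{idx:02d}",
                member_ids=tuple(m.patient_id for m in members),
                outcome=outcome,
                covariate_matrix=np.vstack(cov_rows),
                targets=np.vstack(target_rows),
                member_statics=tuple(statics),
                member_records=tuple(members),
                grid_length=grid_length,
                channels=members[0].channels,
            ))
    return triplets


def fit_triplet_gprs(triplet: Triplet, L: float, jitter_scale: float = 1e-6,
                     convention: str = "as_printed") -> TripletGPR:
    """Fit the triplet's 8 GP regressors (one per perfusion variable).

    Each regressor conditions an RBF(L) prior on the stacked (covariate, value)
    pairs of the three members.  A small observation-noise jitter —
    ``jitter_scale`` times the target variance — is added to the kernel
    diagonal for numerical stability.
    """
    K0 = rbf_kernel_matrix(triplet.covariate_matrix, triplet.covariate_matrix,
                           L, convention)
    regressors = []
    for v, ch in enumerate(triplet.channels):
        y = triplet.targets[:, v]
        jitter = jitter_scale * max(float(np.var(y)), 1.0)
        K = K0.copy()
        K[np.diag_indices_from(K)] += jitter
        try:
            chol = cho_factor(K, lower=True)
        except LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"triplet {triplet.triplet_id}, channel '{ch}': kernel matrix "
                f"singular even after jitter {jitter:g} (L={L})") from err
        regressors.append(_VariableGP(channel=ch, jitter=jitter, chol=chol,
                                      alpha=cho_solve(chol, y)))
    return TripletGPR(triplet=triplet, length_scale=float(L),
                      convention=convention, regressors=regressors)


def sample_synthetic_cohort(gprs: list[TripletGPR], draws_success: int = 3,
                            draws_fail: int = 18,
                            rng: np.random.Generator | None = None,
                            ) -> list[PatientRecord]:
    """Sample synthetic patients from fitted triplet GPs.

    Successful triplets are sampled ``draws_success`` times each and
    unsuccessful triplets ``draws_fail`` times (defaults 3 and 18: with 30
    successful and 8 unsuccessful triplets that is 90 + 144 = 234 synthetic
    patients).  Draw ``j`` of a triplet evaluates the joint posterior over the
    full time grid at member ``j mod 3``'s covariates and copies that member's
    static variables; the label is the triplet's shared outcome.
    """
    if draws_success < 1 or draws_fail < 1:
        raise ValueError("draws per triplet must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    records = []
    for g in gprs:
        trip = g.triplet
        n_draws = draws_success if trip.outcome == 1 else draws_fail
        per_member = [[] for _ in range(3)]
        for j in range(n_draws):
            per_member[j % 3].append(j)
        for m, draw_ids in enumerate(per_member):
            if not draw_ids:
                continue
            values = g.sample(m, len(draw_ids), rng)
            src = trip.member_records[m]
            T = trip.grid_length
            times = (np.arange(T) + 1) * (src.run_seconds / T)
            for values_j, j in zip(values, draw_ids):
                records.append(PatientRecord(
                    patient_id=f"{trip.triplet_id}-{j:02d}",
                    outcome=trip.outcome,
                    age=src.age, sex=src.sex, bmi=src.bmi, cause=src.cause,
                    arrest_pre_ecmo=src.arrest_pre_ecmo,
                    shock_pre_ecmo=src.shock_pre_ecmo,
                    reinfusion_site=src.reinfusion_site,
                    drainage_site=src.drainage_site,
                    reinfusion_size=src.reinfusion_size,
                    drainage_size=src.drainage_size,
                    ventilation_type=src.ventilation_type,
                    times=times, perfusion=values_j, channels=trip.channels,
                ))
    records.sort(key=lambda r: r.patient_id)
    return records


@dataclass
class SyntheticFoldPlan:
    """Triplet-level group assignment for synthetic cross-validation."""

    groups: list          # n_groups lists of triplet ids
    excluded: list        # triplet ids left out of this iteration
    draws_success: int = 3
    draws_fail: int = 18

    def splits(self):
        """Rotate the test group over all positions -> (train, val, test) id lists."""
        n = len(self.groups)
        for k in range(n):
            test = list(self.groups[k])
            val = list(self.groups[(k + 1) % n])
            train = [t for i, g in enumerate(self.groups)
                     if i not in (k, (k + 1) % n) for t in g]
            yield train, val, test

    def patient_groups(self, records: list[PatientRecord]) -> list[list[str]]:
        """Expand triplet groups to synthetic patient-id groups."""
        by_triplet: dict[str, list[str]] = {}
        for r in records:
            by_triplet.setdefault(r.patient_id.rsplit("-", 1)[0], []).append(r.patient_id)
        return [[pid for t in group for pid in by_triplet.get(t, [])]
                for group in self.groups]


def split_synthetic_folds(triplets: list[Triplet], rng: np.random.Generator,
                          n_groups: int = 5, succ_per_group: int = 6,
                          fail_per_group: int = 1, draws_success: int = 3,
                          draws_fail: int = 18) -> SyntheticFoldPlan:
    """Randomize triplets into balanced groups (default: 5 groups of 6 + 1).

    Surplus triplets of either outcome are excluded at random each iteration
    so every group has identical composition; with the defaults each group
    expands to 6*3 + 1*18 = 36 synthetic patients.
    """
    succ = [t.triplet_id for t in triplets if t.outcome == 1]
    fail = [t.triplet_id for t in triplets if t.outcome == 0]
    need_s, need_f = n_groups * succ_per_group, n_groups * fail_per_group
    if len(succ) < need_s or len(fail) < need_f:
        raise ValueError(
            f"need >= {need_s} successful and >= {need_f} unsuccessful triplets, "
            f"got {len(succ)} and {len(fail)}")
    succ = list(rng.permutation(succ))
    fail = list(rng.permutation(fail))
    excluded = succ[need_s:] + fail[need_f:]
    groups = []
    for g in range(n_groups):
        groups.append(succ[g * succ_per_group:(g + 1) * succ_per_group]
                      + fail[g * fail_per_group:(g + 1) * fail_per_group])
    return SyntheticFoldPlan(groups=groups, excluded=excluded,
                             draws_success=draws_success, draws_fail=draws_fail)
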