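"""Inverse Jacobian inference from metabolite covariance.

Near a metabolic steady state, intrinsic fluctuations of metabolite
concentrations behave as a linear (Ornstein--Uhlenbeck) stochastic process
whose stationary covariance ``C`` is tied to the biochemical Jacobian ``J``
and the diagonal fluctuation matrix ``D`` by the Lyapunov equation

    J C + C J^T = -2 D.

Given ``C`` estimated from biological replicates and a structural mask of
allowed Jacobian entries (derived from the metabolic interaction matrix),
the inverse problem is linear in the masked entries of ``J`` and is solved
by total least squares.  Because ``D`` is unknown, a stochastic ensemble of
solutions is computed over random diagonal fluctuation matrices; the
ensemble is summarized entrywise as median / IQR^2, and two metabolic states
are compared through the differential Jacobian ``|log2 |J_a,norm / J_b,norm||``
with per-entry significance tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats


class InferenceError(ValueError):
    """Invalid input to an inference operation."""


class SolverError(RuntimeError):
    """The Lyapunov or inverse solver could not produce a solution."""


# --------------------------------------------------------------------------
# data containers


@dataclass
class MetaboliteDataset:
    """Replicate x pool table of (relative) metabolite concentrations."""

    pool_ids: list
    values: np.ndarray  # shape (n_replicates, n_pools)
    condition_label: str = ""
    #: number of replicate rows dropped for missing cells during ingestion
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.pool_ids):
            raise InferenceError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.pool_ids)} pools"
            )
        if np.isnan(self.values).any():
            raise InferenceError("dataset contains missing cells after ingestion")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, condition_label: str = "") -> "MetaboliteDataset":
        """Build a dataset from a replicate table, dropping rows with missing cells."""
        complete = df.dropna(axis=0, how="any")
        n_dropped = len(df) - len(complete)
        if n_dropped:
            warnings.warn(
                f"dropped {n_dropped} replicate row(s) with missing cells",
                stacklevel=2,
            )
        return cls(
            pool_ids=list(df.columns),
            values=complete.to_numpy(dtype=float),
            condition_label=condition_label,
            n_dropped=n_dropped,
        )

    @classmethod
    def read_table(cls, path, condition_label: str = "") -> "MetaboliteDataset":
        """Read a delimited replicate table (comma or tab; sniffed)."""
        df = pd.read_csv(path, sep=None, engine="python")
        return cls.from_dataframe(df, condition_label=condition_label)


@dataclass
class CovarianceMatrix:
    pool_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.pool_ids)
        if self.values.shape != (n, n):
            raise InferenceError(f"covariance shape {self.values.shape}, expected ({n},{n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise InferenceError("covariance matrix is not symmetric")
        if np.any(np.diag(self.values) < 0):
            raise InferenceError("negative variance on the diagonal")
        w = np.linalg.eigvalsh(self.values)
        scale = max(w.max(), 0.0)
        if w.min() < -1e-9 * max(scale, 1e-300):
            raise InferenceError(
                f"covariance not positive semidefinite (min eigenvalue {w.min():g})"
            )


@dataclass
class FluctuationMatrix:
    """Diagonal matrix of intrinsic noise intensities."""

    diagonal: np.ndarray

    def __post_init__(self) -> None:
        self.diagonal = np.asarray(self.diagonal, dtype=float)
        if self.diagonal.ndim != 1:
            raise InferenceError("fluctuation matrix is specified by its diagonal")

    @property
    def values(self) -> np.ndarray:
        return np.diag(self.diagonal)


@dataclass
class JacobianMatrix:
    pool_ids: list
    values: np.ndarray
    structure_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.structure_mask = np.asarray(self.structure_mask, dtype=bool)
        n = len(self.pool_ids)
        if self.values.shape != (n, n) or self.structure_mask.shape != (n, n):
            raise InferenceError("Jacobian and mask must be square over pool_ids")
        if np.any(self.values[~self.structure_mask] != 0.0):
            raise InferenceError("nonzero Jacobian entry outside the structure mask")


@dataclass
class InverseSolution:
    """One masked inverse-Lyapunov solve with its quality certificate."""

    jacobian: JacobianMatrix
    #: Frobenius norm of J C + C J^T + 2 D
    lyapunov_residual: float
    #: effective rank of the restricted linear operator
    operator_rank: int
    nullspace_dim: int
    method: str  # "tls" or "ols_fallback"


@dataclass
class JacobianEnsemble:
    pool_ids: list
    structure_mask: np.ndarray
    #: shape (n_samples, n_pools, n_pools)
    samples: np.ndarray
    n_iterations: int
    seed: int
    n_failed: int = 0
    failure_causes: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass
class NormalizedJacobian:
    pool_ids: list
    structure_mask: np.ndarray
    median_matrix: np.ndarray
    iqr_matrix: np.ndarray
    #: median / IQR^2; NaN where undefined (IQR below tolerance or off-mask)
    normalized_matrix: np.ndarray

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.normalized_matrix)


@dataclass
class DifferentialJacobian:
    """Elementwise |log2 |J_a,norm / J_b,norm|| between two metabolic states."""

    pool_ids: list
    entries: np.ndarray  # NaN where undefined
    pvalues: np.ndarray | None = None
    significance_mask: np.ndarray | None = None
    alpha: float | None = None

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.entries)

    def ranked_entries(self) -> list:
        """Defined entries sorted by decreasing dJ, as (i, j, value) tuples."""
        idx = np.argwhere(self.defined_mask)
        vals = self.entries[self.defined_mask]
        order = np.argsort(-vals, kind="stable")
        return [(int(idx[k, 0]), int(idx[k, 1]), float(vals[k])) for k in order]


@dataclass
class SignificanceResult:
    pool_ids: list
    pvalues: np.ndarray
    significant: np.ndarray
    alpha: float
    effective_n: int
    procedure: str  # "batch_median" or "full"
    fdr: str = "none"


# --------------------------------------------------------------------------
# operations


def covariance_from_replicates(dataset: MetaboliteDataset) -> CovarianceMatrix:
    """Unbiased (n-1) sample covariance of the replicate table."""
    if dataset.n_replicates < 2:
        raise InferenceError(
            f"covariance needs at least 2 replicates, got {dataset.n_replicates}"
        )
    cov = np.cov(dataset.values, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    cov = (cov + cov.T) / 2.0
    if not cov.any():
        warnings.warn(
            "constant dataset: covariance is identically zero; "
            "inverse solves on it will fail",
            stacklevel=2,
        )
    return CovarianceMatrix(pool_ids=list(dataset.pool_ids), values=cov)


def shrink_covariance(cov: CovarianceMatrix, intensity: float) -> CovarianceMatrix:
    """Linear shrinkage toward the diagonal: (1-a) C + a diag(C)."""
    if not 0.0 <= intensity <= 1.0:
        raise InferenceError("shrinkage intensity must lie in [0, 1]")
    v = (1.0 - intensity) * cov.values + intensity * np.diag(np.diag(cov.values))
    return CovarianceMatrix(pool_ids=list(cov.pool_ids), values=v)


def sample_fluctuation_matrix(dim: int, rng, signed: bool = False) -> FluctuationMatrix:
    """Draw a random diagonal fluctuation matrix.

    Diagonal entries are standard-normal draws.  By default their absolute
    values are taken (half-normal), since the noise intensity of a stationary
    stochastic process must be positive; ``signed=True`` keeps the literal
    signed draws.

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed.
    """
    if dim < 1:
        raise InferenceError("dimension must be at least 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    d = rng.standard_normal(dim)
    if not signed:
        d = np.abs(d)
    return FluctuationMatrix(diagonal=d)


def _require_hurwitz(J: np.ndarray) -> None:
    w = np.linalg.eigvals(J)
    worst = w[np.argmax(w.real)]
    if worst.real >= 0:
        raise SolverError(
            f"Jacobian is not Hurwitz-stable: eigenvalue {worst:g} has "
            "non-negative real part, no stationary covariance exists"
        )


def forward_lyapunov(J, D) -> np.ndarray:
    """Solve J C + C J^T = -2 D for the stationary covariance C.

    ``J`` may be a :class:`JacobianMatrix` or a plain array; ``D`` a
    :class:`FluctuationMatrix` or a plain diagonal/square array.  ``J`` must
    be Hurwitz-stable.  The residual is verified against a relative
    tolerance of 1e-9.
    """
    Jm = J.values if isinstance(J, JacobianMatrix) else np.asarray(J, dtype=float)
    if isinstance(D, FluctuationMatrix):
        Dm = D.values
    else:
        Dm = np.asarray(D, dtype=float)
        if Dm.ndim == 1:
            Dm = np.diag(Dm)
    _require_hurwitz(Jm)
    C = scipy.linalg.solve_continuous_lyapunov(Jm, -2.0 * Dm)
    C = (C + C.T) / 2.0
    resid = np.linalg.norm(Jm @ C + C @ Jm.T + 2.0 * Dm, "fro")
    scale = np.linalg.norm(Jm, "fro") * np.linalg.norm(C, "fro") + np.linalg.norm(Dm, "fro")
    if resid > 1e-9 * max(scale, 1e-300):
        raise SolverError(
            f"Lyapunov solve failed residual check ({resid:g} > 1e-9 * {scale:g}); "
            "the Lyapunov operator is numerically singular"
        )
    return C


def structure_mask_from_interactions(matrix_values: np.ndarray) -> np.ndarray:
    """Allowed Jacobian entries implied by an interaction matrix.

    ``J[i, j]`` may be nonzero when species i and j participate in at least
    one common interaction (a change in j then perturbs a rate that moves i);
    the diagonal is allowed for any species touching an interaction.
    """
    part = np.asarray(matrix_values) != 0.0
    return (part.astype(int) @ part.astype(int).T) > 0


def _restricted_operator(C: np.ndarray, mask: np.ndarray) -> tuple:
    """Columns of vec(J C + C J^T) restricted to masked entries of J.

    For the basis matrix E_ij, the contribution is E_ij C + C E_ji; its
    vectorization forms one column of the operator A in A x = -2 vec(D).
    """
    n = C.shape[0]
    rows, cols = np.nonzero(mask)
    A = np.zeros((n * n, rows.size))
    for k, (i, j) in enumerate(zip(rows, cols)):
        M = np.zeros((n, n))
        M[i, :] += C[j, :]   # E_ij C adds row j of C into row i
        M[:, i] += C[:, j]   # C E_ji adds column j of C into column i
        A[:, k] = M.ravel()
    return A, rows, cols


def inverse_jacobian(
    C,
    D,
    mask: np.ndarray,
    pool_ids=None,
    rank_tol: float = 1e-10,
) -> InverseSolution:
    """Solve the inverse Lyapunov problem for a structurally masked Jacobian.

    Minimizes the total-least-squares discrepancy of the linear system
    ``A x = -2 vec(D)`` where ``A`` maps the masked entries ``x`` of ``J``
    through ``J C + C J^T``.  When the TLS construction is ill-posed (rank
    deficient operator or degenerate smallest singular value) the solver
    falls back to the minimum-norm ordinary least-squares solution and flags
    it.  Entries outside the mask are exactly zero; the Lyapunov residual,
    the operator's effective rank and its null-space dimension are reported
    with the estimate.
    """
    Cm = C.values if isinstance(C, CovarianceMatrix) else np.asarray(C, dtype=float)
    if isinstance(D, FluctuationMatrix):
        Dm = D.values
    else:
        Dm = np.asarray(D, dtype=float)
        if Dm.ndim == 1:
            Dm = np.diag(Dm)
    mask = np.asarray(mask, dtype=bool)
    n = Cm.shape[0]
    if pool_ids is None:
        pool_ids = (
            list(C.pool_ids) if isinstance(C, CovarianceMatrix) else [f"x{i}" for i in range(n)]
        )
    if mask.shape != (n, n):
        raise InferenceError(f"mask shape {mask.shape} does not match dimension {n}")
    if not mask.any():
        raise InferenceError("structure mask allows no entries")
    if not Cm.any():
        raise SolverError("zero covariance matrix: no fluctuation information")

    A, rows, cols = _restricted_operator(Cm, mask)
    b = (-2.0 * Dm).ravel()
    m = A.shape[1]

    sA = np.linalg.svd(A, compute_uv=False)
    op_scale = sA[0] if sA.size else 0.0
    rank = int(np.sum(sA > rank_tol * max(op_scale, 1e-300)))
    if rank == 0:
        raise SolverError("restricted Lyapunov operator has rank 0")
    nullspace_dim = m - rank

    method = "tls"
    x = None
    if rank == m:
        # classical TLS via the SVD of the augmented system [A | b]
        U, s, Vt = np.linalg.svd(np.column_stack([A, b]))
        v = Vt[-1]
        degenerate = (
            abs(v[m]) <= 1e-12
            or (s.size > 1 and s[-2] - s[-1] <= 1e-10 * max(s[0], 1e-300))
        )
        if not degenerate:
            x = -v[:m] / v[m]
    if x is None:
        method = "ols_fallback"
        x = np.linalg.lstsq(A, b, rcond=rank_tol)[0]

    J = np.zeros((n, n))
    J[rows, cols] = x
    resid = np.linalg.norm(J @ Cm + Cm @ J.T + 2.0 * Dm, "fro")
    return InverseSolution(
        jacobian=JacobianMatrix(pool_ids=list(pool_ids), values=J, structure_mask=mask),
        lyapunov_residual=float(resid),
        operator_rank=rank,
        nullspace_dim=nullspace_dim,
        method=method,
    )


def run_ensemble(
    C,
    mask: np.ndarray,
    n_iterations: int,
    seed: int,
    pool_ids=None,
    signed_d: bool = False,
) -> JacobianEnsemble:
    """Stochastic ensemble of inverse solutions over random fluctuation matrices.

    Each iteration draws an independent diagonal ``D`` (half-normal by
    default; ``signed_d=True`` reproduces literal standard-normal draws) from
    an independent child stream of ``seed`` and solves the masked inverse
    problem.  Iterations whose solve fails are excluded and counted.
    Identical seeds reproduce the ensemble bit-exactly.
    """
    if n_iterations < 1:
        raise InferenceError("n_iterations must be at least 1")
    Cm = C.values if isinstance(C, CovarianceMatrix) else np.asarray(C, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n = Cm.shape[0]
    if pool_ids is None:
        pool_ids = (
            list(C.pool_ids) if isinstance(C, CovarianceMatrix) else [f"x{i}" for i in range(n)]
        )
    if not Cm.any():
        raise SolverError("zero covariance matrix: no fluctuation information")

    # the operator depends only on C and the mask: build it once
    A, rows, cols = _restricted_operator(Cm, mask)
    m = A.shape[1]
    sA = np.linalg.svd(A, compute_uv=False)
    rank = int(np.sum(sA > 1e-10 * max(sA[0], 1e-300)))
    if rank == 0:
        raise SolverError("restricted Lyapunov operator has rank 0")

    streams = np.random.SeedSequence(seed).spawn(n_iterations)
    samples = []
    n_failed = 0
    causes: dict = {}
    fallbacks = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        D = sample_fluctuation_matrix(n, rng, signed=signed_d)
        b = (-2.0 * D.values).ravel()
        try:
            x = None
            method = "tls"
            if rank == m:
                U, s, Vt = np.linalg.svd(np.column_stack([A, b]))
                v = Vt[-1]
                if abs(v[m]) > 1e-12 and (
                    s.size < 2 or s[-2] - s[-1] > 1e-10 * max(s[0], 1e-300)
                ):
                    x = -v[:m] / v[m]
            if x is None:
                method = "ols_fallback"
                x = np.linalg.lstsq(A, b, rcond=1e-10)[0]
            if not np.all(np.isfinite(x)):
                raise SolverError("non-finite solution")
            if method == "ols_fallback":
                fallbacks += 1
            J = np.zeros((n, n))
            J[rows, cols] = x
            samples.append(J)
        except (SolverError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            key = type(exc).__name__
            causes[key] = causes.get(key, 0) + 1
    if not samples:
        dominant = max(causes, key=causes.get)
        raise SolverError(f"all {n_iterations} iterations failed (dominant cause: {dominant})")
    return JacobianEnsemble(
        pool_ids=list(pool_ids),
        structure_mask=mask,
        samples=np.array(samples),
        n_iterations=n_iterations,
        seed=seed,
        n_failed=n_failed,
        failure_causes=causes,
        metadata={
            "d_sign_policy": "signed" if signed_d else "abs",
            "operator_rank": rank,
            "nullspace_dim": m - rank,
            "ols_fallbacks": fallbacks,
        },
    )


def normalize_ensemble(ensemble: JacobianEnsemble, iqr_tol: float = 1e-12) -> NormalizedJacobian:
    """Summarize an ensemble elementwise as median / IQR^2.

    The interquartile range uses the linear-interpolation quantile rule.
    Entries whose IQR falls below ``iqr_tol`` (including everything outside
    the structure mask) are flagged undefined (NaN), never infinite.
    """
    if ensemble.n_samples < 3:
        raise InferenceError(
            f"quartiles need at least 3 samples, got {ensemble.n_samples}"
        )
    med = np.median(ensemble.samples, axis=0)
    q1, q3 = np.quantile(ensemble.samples, [0.25, 0.75], axis=0, method="linear")
    iqr = q3 - q1
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = med / iqr**2
    norm[iqr < iqr_tol] = np.nan
    norm[~ensemble.structure_mask] = np.nan
    return NormalizedJacobian(
        pool_ids=list(ensemble.pool_ids),
        structure_mask=ensemble.structure_mask,
        median_matrix=med,
        iqr_matrix=iqr,
        normalized_matrix=norm,
    )


def differential_jacobian(a: NormalizedJacobian, b: NormalizedJacobian) -> DifferentialJacobian:
    """Differential Jacobian dJ_ij = |log2 |a_ij / b_ij|| between two states.

    Entries undefined in either input, or with a zero in either state (the
    log-ratio is then infinite), are flagged undefined.  Swapping the two
    states leaves every defined entry unchanged.
    """
    if list(a.pool_ids) != list(b.pool_ids):
        raise InferenceError("pool ordering mismatch between the two states")
    with np.errstate(divide="ignore", invalid="ignore"):
        # |log2(|a|) - log2(|b|)| rather than |log2|a/b||: mathematically
        # identical, but bit-exactly symmetric under swapping the two states
        dj = np.abs(np.log2(np.abs(a.normalized_matrix)) - np.log2(np.abs(b.normalized_matrix)))
    dj[~np.isfinite(dj)] = np.nan
    return DifferentialJacobian(pool_ids=list(a.pool_ids), entries=dj)


def welch_t(x: np.ndarray, y: np.ndarray, axis: int = 0) -> tuple:
    """Welch's unequal-variance t statistic and Welch--Satterthwaite p-value."""
    t, p = scipy.stats.ttest_ind(x, y, axis=axis, equal_var=False)
    return t, p


def entry_significance(
    ens_a: JacobianEnsemble,
    ens_b: JacobianEnsemble,
    alpha: float = 0.05,
    procedure: str = "batch_median",
    n_batches: int = 100,
    fdr: str = "none",
) -> SignificanceResult:
    """Per-entry two-sample test between two Jacobian ensembles.

    With ``procedure="batch_median"`` (default) each ensemble is partitioned
    into ``n_batches`` batches and Welch's t-test is applied to the batch
    medians, avoiding the spurious significance that raw tests on very large
    ensembles produce; ``procedure="full"`` tests the literal ensembles.
    ``fdr="bh"`` applies Benjamini--Hochberg correction across masked entries.
    """
    if list(ens_a.pool_ids) != list(ens_b.pool_ids):
        raise InferenceError("pool ordering mismatch between ensembles")
    if not np.array_equal(ens_a.structure_mask, ens_b.structure_mask):
        raise InferenceError("structure mask mismatch between ensembles")
    if procedure not in ("batch_median", "full"):
        raise InferenceError(f"unknown procedure {procedure!r}")

    def _batched(samples: np.ndarray) -> np.ndarray:
        k = samples.shape[0]
        nb = min(n_batches, k)
        usable = (k // nb) * nb
        return np.median(samples[:usable].reshape(nb, usable // nb, *samples.shape[1:]), axis=1)

    if procedure == "batch_median":
        xa, xb = _batched(ens_a.samples), _batched(ens_b.samples)
    else:
        xa, xb = ens_a.samples, ens_b.samples
    effective_n = xa.shape[0]

    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-variance entries yield NaN
            _, p = welch_t(xa, xb, axis=0)
    p = np.asarray(p, dtype=float)
    p[~ens_a.structure_mask] = np.nan

    mask = ens_a.structure_mask & np.isfinite(p)
    if fdr == "bh":
        flat = p[mask]
        order = np.argsort(flat)
        ranked = flat[order]
        mtot = flat.size
        adj = np.minimum.accumulate((ranked * mtot / np.arange(1, mtot + 1))[::-1])[::-1]
        adj = np.clip(adj, 0.0, 1.0)
        out = np.full_like(flat, np.nan)
        out[order] = adj
        p[mask] = out
    elif fdr != "none":
        raise InferenceError(f"unknown fdr mode {fdr!r}")

    significant = np.zeros_like(p, dtype=bool)
    significant[mask] = p[mask] < alpha
    return SignificanceResult(
        pool_ids=list(ens_a.pool_ids),
        pvalues=p,
        significant=significant,
        alpha=alpha,
        effective_n=effective_n,
        procedure=procedure,
        fdr=fdr,
    )
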