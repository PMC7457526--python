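"""Working correlation structures, including the Kronecker (separable) form.

A GEE working correlation R describes the within-cluster dependence of the
m = J*K observations per subject.  Besides the classic structures
(independence, AR1, compound symmetry, unstructured) this module builds the
separable structure R = B (x) Sigma, with B the J x J condition-level and
Sigma the K x K channel-level correlation matrix — the natural model when
the same K channels are recorded under each of J conditions and channel
correlation decays with distance.

Both Kronecker factors are constrained to unit diagonal: a separable
covariance is only identified up to a scalar, and overall residual scale
lives in the variance function and dispersion, not in R.

Parameters are estimated from Pearson residuals by method of moments, with
numerator and denominator pooled globally over the same index set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CorrelationError",
    "WorkingCorrelation",
    "build_ar1",
    "build_cs",
    "estimate_working_correlation",
    "kronecker_correlation",
]

#: AR1 coefficient estimates are clipped to this range to keep R invertible.
AR1_CLIP = 0.99
#: Eigenvalue floor applied when repairing a non-positive-definite estimate.
PD_FLOOR = 1.0e-6
#: Smallest admissible eigenvalue of a realized working correlation.
PD_TOL = 1.0e-10

_KINDS = {"independence", "ar1", "cs", "unstructured", "kronecker"}
_B_SPECS = {"unstructured", "independence"}
_SIGMA_SPECS = {"ar1", "cs", "unstructured"}


class CorrelationError(ValueError):
    """Invalid correlation specification or failed parameter estimation."""


def build_ar1(dim: int, rho: float) -> np.ndarray:
    """First-order autoregressive correlation: entry (s, t) = rho**|s-t|."""
    if not -1.0 < rho < 1.0:
        raise CorrelationError(f"AR1 coefficient must satisfy |rho| < 1, got {rho}")
    idx = np.arange(dim)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def build_cs(dim: int, rho: float) -> np.ndarray:
    """Compound-symmetry (exchangeable) correlation with off-diagonal rho."""
    lower = -1.0 / (dim - 1) if dim > 1 else -1.0
    if not lower < rho < 1.0:
        raise CorrelationError(
            f"CS coefficient must lie in ({lower:.4g}, 1) for dim {dim}, got {rho}"
        )
    R = np.full((dim, dim), float(rho))
    np.fill_diagonal(R, 1.0)
    return R


def _check_correlation(M: np.ndarray, name: str) -> None:
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise CorrelationError(f"{name} must be square")
    if np.max(np.abs(np.diag(M) - 1.0)) > 1e-8:
        raise CorrelationError(f"{name} must have unit diagonal")
    if np.max(np.abs(M - M.T)) > 1e-8:
        raise CorrelationError(f"{name} must be symmetric")


def kronecker_correlation(B: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Separable correlation B (x) Sigma in condition-major order.

    Entry ((j, k), (j', k')) equals ``B[j, j'] * Sigma[k, k']``, matching
    the condition-major vectorization of the cluster.
    """
    B = np.asarray(B, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    _check_correlation(B, "condition factor B")
    _check_correlation(Sigma, "channel factor Sigma")
    return np.kron(B, Sigma)


def _unit_rescale(M: np.ndarray) -> np.ndarray:
    """Rescale a covariance-like symmetric matrix to unit diagonal."""
    d = np.sqrt(np.diag(M))
    if np.any(d <= 0):
        raise CorrelationError("cannot rescale: non-positive diagonal")
    R = M / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return 0.5 * (R + R.T)


def _pd_repair(R: np.ndarray) -> np.ndarray:
    """Floor eigenvalues at PD_FLOOR and restore the unit diagonal."""
    w = np.linalg.eigvalsh(R)
    if w[0] > PD_TOL:
        return R
    vals, vecs = np.linalg.eigh(R)
    vals = np.maximum(vals, PD_FLOOR)
    fixed = (vecs * vals) @ vecs.T
    fixed = _unit_rescale(fixed)
    if np.linalg.eigvalsh(fixed)[0] <= 0:
        raise CorrelationError("correlation estimate not repairable to PD")
    return fixed


@dataclass(frozen=True)
class WorkingCorrelation:
    """Specification plus (optionally) estimated parameters of R.

    ``kind`` is one of independence | ar1 | cs | unstructured | kronecker;
    a Kronecker structure additionally names its condition-side spec
    (``unstructured`` or ``independence``) and channel-side spec (``ar1``,
    ``cs`` or ``unstructured``).  ``dims = (J, K)`` fixes the cluster grid;
    for non-Kronecker kinds the realized matrix has dimension m = J*K over
    the full condition-major vector.
    """

    kind: str
    dims: tuple[int, int]
    condition_spec: str | None = None
    channel_spec: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise CorrelationError(f"unknown correlation kind {self.kind!r}")
        if self.kind == "kronecker":
            if self.condition_spec not in _B_SPECS:
                raise CorrelationError(
                    f"condition-side spec must be one of {sorted(_B_SPECS)}"
                )
            if self.channel_spec not in _SIGMA_SPECS:
                raise CorrelationError(
                    f"channel-side spec must be one of {sorted(_SIGMA_SPECS)}"
                )
        J, K = self.dims
        if J < 1 or K < 1:
            raise CorrelationError("dims must be positive")

    @property
    def dim(self) -> int:
        return self.dims[0] * self.dims[1]

    @staticmethod
    def from_string(spec: str, dims: tuple[int, int]) -> "WorkingCorrelation":
        """Parse ``"independence" | "ar1" | "cs" | "unstructured" |
        "kron:<B-spec>,<Sigma-spec>"`` (e.g. ``"kron:unstructured,ar1"``)."""
        spec = spec.strip().lower()
        if spec.startswith("kron:"):
            parts = spec[len("kron:"):].split(",")
            if len(parts) != 2:
                raise CorrelationError(
                    "kronecker spec must be 'kron:<B-spec>,<Sigma-spec>'"
                )
            return WorkingCorrelation(
                kind="kronecker",
                dims=dims,
                condition_spec=parts[0].strip(),
                channel_spec=parts[1].strip(),
            )
        return WorkingCorrelation(kind=spec, dims=dims)

    def to_string(self) -> str:
        if self.kind == "kronecker":
            return f"kron:{self.condition_spec},{self.channel_spec}"
        return self.kind

    def matrix(self) -> np.ndarray:
        """Realize R from the stored parameters (identity if none needed)."""
        m = self.dim
        if self.kind == "independence":
            return np.eye(m)
        if self.kind == "ar1":
            return build_ar1(m, self.params.get("rho", 0.0))
        if self.kind == "cs":
            return build_cs(m, self.params.get("rho", 0.0))
        if self.kind == "unstructured":
            R = np.asarray(self.params.get("R", np.eye(m)), dtype=float)
            _check_correlation(R, "unstructured R")
            return R
        # kronecker; factors are PD by construction (clipped coefficients,
        # repaired unstructured estimates), so skip re-validation here
        J, K = self.dims
        if self.condition_spec == "independence":
            B = np.eye(J)
        else:
            B = np.asarray(self.params.get("B", np.eye(J)), dtype=float)
        if self.channel_spec == "ar1":
            Sigma = build_ar1(K, self.params.get("sigma_rho", 0.0))
        elif self.channel_spec == "cs":
            Sigma = build_cs(K, self.params.get("sigma_rho", 0.0))
        else:
            Sigma = np.asarray(self.params.get("Sigma", np.eye(K)), dtype=float)
        return (B[:, None, :, None] * Sigma[None, :, None, :]).reshape(J * K, J * K)


def _clip_cs(rho: float, dim: int) -> float:
    lower = -1.0 / (dim - 1) + 1e-6 if dim > 1 else -AR1_CLIP
    return float(np.clip(rho, lower, AR1_CLIP))


def estimate_working_correlation(
    residuals: np.ndarray, spec: WorkingCorrelation
) -> WorkingCorrelation:
    """Moment-estimate correlation parameters from Pearson residuals.

    Parameters
    ----------
    residuals : ndarray, shape (n, J*K) or (n, J, K)
        Pearson residuals at the current coefficient iterate, one row per
        subject in condition-major order.
    spec
        Structure to estimate; returned with ``params`` filled.

    Notes
    -----
    All estimators are global-pooling moment ratios: a mean of residual
    cross-products over the relevant index set divided by the overall mean
    squared residual (which also makes them invariant to residual scale).
    AR1 and CS channel coefficients use within-condition pairs; the
    condition factor B uses same-channel cross-condition pairs.  Estimated
    coefficients are clipped to their positive-definite ranges and any
    unstructured estimate that is still non-PD is repaired by flooring its
    eigenvalues at 1e-6 and rescaling to unit diagonal.
    """
    J, K = spec.dims
    e = np.asarray(residuals, dtype=float)
    if e.ndim == 2:
        e = e.reshape(e.shape[0], J, K)
    if e.shape[1:] != (J, K):
        raise CorrelationError(
            f"residuals have shape {residuals.shape}, expected (n, {J}, {K})"
        )
    n = e.shape[0]
    if n < 2:
        raise CorrelationError("correlation estimation needs at least 2 subjects")

    msq = float(np.mean(e**2))
    if msq <= 0:
        raise CorrelationError("all residuals are zero")
    flat = e.reshape(n, J * K)

    def ar1_rho() -> float:
        num = float(np.mean(e[:, :, :-1] * e[:, :, 1:]))
        return float(np.clip(num / msq, -AR1_CLIP, AR1_CLIP))

    if spec.kind == "independence":
        return replace(spec, params={})

    if spec.kind == "ar1":
        return replace(spec, params={"rho": ar1_rho()})

    if spec.kind == "cs":
        m = J * K
        prod = flat.T @ flat / n
        off = (prod.sum() - np.trace(prod)) / (m * (m - 1))
        return replace(spec, params={"rho": _clip_cs(off / msq, m)})

    if spec.kind == "unstructured":
        R = _unit_rescale(flat.T @ flat / n)
        return replace(spec, params={"R": _pd_repair(R)})

    # kronecker
    params: dict = {}
    if spec.condition_spec == "unstructured":
        # B[j, j'] from same-channel cross-condition products, pooled over (i, k)
        Bhat = np.einsum("ijk,ilk->jl", e, e) / (n * K)
        params["B"] = _pd_repair(_unit_rescale(Bhat))
    if spec.channel_spec == "ar1":
        params["sigma_rho"] = ar1_rho()
    elif spec.channel_spec == "cs":
        prod = np.einsum("ijk,ijl->kl", e, e) / (n * J)
        off = (prod.sum() - np.trace(prod)) / (K * (K - 1))
        params["sigma_rho"] = _clip_cs(off / msq, K)
    else:
        Shat = np.einsum("ijk,ijl->kl", e, e) / (n * J)
        params["Sigma"] = _pd_repair(_unit_rescale(Shat))
    # the realized Kronecker product of PD factors is PD (spectrum is the
    # pairwise eigenvalue products), so no further repair is needed
    return replace(spec, params=params)
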