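"""Equilibrium allele-frequency spectra under selection against heterozygotes.

Stabilizing selection on a polygenic trait is well approximated, for the
rare alleles that matter here, by a model in which both homozygotes have
relative fitness 1 and heterozygous carriers have fitness ``1 - s_het``.
This module computes the equilibrium distribution of derived-allele counts
of a discrete-time Wright-Fisher (DTWF) population under that scheme with
recurrent mutation, conditioned so that the derived allele cannot fix
(the ancestral allele is assumed known; the fixation state is deleted and
transition rows renormalized).

A note on the numerics: the fitness scheme is formally underdominant, so
the renormalized chain possesses a second, biologically meaningless
quasi-stationary lump just below fixation.  For strong selection the exact
stationary vector of the renormalized matrix puts essentially all of its
mass in that lump, behind a probability barrier of order exp(-N*s_het),
and a direct linear solve returns it (or floating-point noise).  Alleles
in the real process arise by mutation from the ancestral state, so the
meaningful spectrum is the mutation-selection-drift equilibrium reached
from a monomorphic population.  ``compute_equilibrium_afs`` therefore
solves the stationary system directly only when the chain mixes across
the interior (weak selection), and otherwise iterates the distribution
forward from the monomorphic state until it converges; the two backends
agree in the regime where both are valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.special import gammaln

__all__ = [
    "SelectionModel",
    "FrequencyDistribution",
    "SelectionGrid",
    "TrajectoryEnsemble",
    "compute_equilibrium_afs",
    "diffusion_stationary_afs",
    "closed_form_balance",
    "simulate_trajectories",
    "nearest_spectrum",
    "desk_scale_model",
]

#: Number of haploid genomes in the reference population of 20,000 diploids.
REFERENCE_TWO_N = 40_000
#: Per-site per-generation mutation rate used throughout.
DEFAULT_MU = 1.25e-8
#: Hard guard on the DTWF state-space size.
MAX_TWO_N = 20_000

# Selection strength (2N * s_het on the haploid scale) above which the direct
# stationary solve of the renormalized chain is numerically untrustworthy and
# forward iteration from the monomorphic state is used instead.
_BACKEND_SWITCH_NS = 10.0


@dataclass(frozen=True)
class SelectionModel:
    """Parameters of the one-locus heterozygote-selection model.

    Parameters
    ----------
    s_het:
        Fitness reduction of heterozygous carriers, in [0, 1].
    mu:
        Per-site per-generation mutation rate (symmetric, recurrent).
    two_N:
        Number of haploid genomes (an even integer >= 4).
    """

    s_het: float
    mu: float = DEFAULT_MU
    two_N: int = REFERENCE_TWO_N

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_het <= 1.0:
            raise ValueError(f"s_het must be in [0, 1], got {self.s_het}")
        if not 0.0 <= self.mu < 1.0:
            raise ValueError(f"mu must be in [0, 1), got {self.mu}")
        if self.two_N < 4 or self.two_N % 2:
            raise ValueError(f"two_N must be an even integer >= 4, got {self.two_N}")

    @property
    def scaled_selection(self) -> float:
        """two_N * s_het, the drift-scaled selection strength."""
        return self.two_N * self.s_het

    @property
    def scaled_mutation(self) -> float:
        """two_N * mu; 2 * two_N * mu is the usual theta."""
        return self.two_N * self.mu


def desk_scale_model(
    s_het: float,
    mu: float = DEFAULT_MU,
    two_N_ref: int = REFERENCE_TWO_N,
    two_N: int = 4_000,
) -> SelectionModel:
    """Rescale a reference-population model onto a smaller state space.

    Preserves the drift-scaled parameters ``two_N * mu`` and
    ``two_N * s_het`` of the reference population so that spectra computed
    on a tractable chain approximate the reference spectrum.
    """
    scale = two_N_ref / two_N
    return SelectionModel(s_het=min(1.0, s_het * scale), mu=mu * scale, two_N=two_N)


@dataclass(frozen=True)
class FrequencyDistribution:
    """Probability mass over derived-allele counts 0 .. two_N - 1."""

    probs: np.ndarray
    model: SelectionModel

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (self.model.two_N,):
            raise ValueError(
                f"probs must have length two_N={self.model.two_N}, got {p.shape}"
            )
        if np.any(p < 0):
            raise ValueError("negative probability mass")
        if abs(p.sum() - 1.0) > 1e-10:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(self.model.two_N) / self.model.two_N

    def mean_frequency(self) -> float:
        return float(self.probs @ self.frequencies)

    def mean_heterozygosity(self) -> float:
        """E[p(1-p)] over the spectrum."""
        f = self.frequencies
        return float(self.probs @ (f * (1.0 - f)))

    def sample_counts(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw derived-allele counts from the spectrum."""
        return rng.choice(self.model.two_N, size=n, p=self.probs)


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Replicate allele-frequency trajectories (replicates x generations)."""

    frequencies: np.ndarray
    model: SelectionModel


def _post_selection_mutation_freq(f: np.ndarray, s: float, mu: float) -> np.ndarray:
    """Expected next-generation frequency under selection then mutation."""
    w_bar = 1.0 - 2.0 * s * f * (1.0 - f)
    f_sel = (f * f + f * (1.0 - f) * (1.0 - s)) / w_bar
    return f_sel * (1.0 - mu) + (1.0 - f_sel) * mu


def _binom_pmf_window(n: int, p: float, n_sd: float = 12.0) -> tuple[int, np.ndarray]:
    """Binomial(n, p) pmf restricted to mean +/- n_sd standard deviations.

    Returns the first support index and the pmf values on the window.  Mass
    outside the window is below ~1e-30 and dropped; rows are renormalized by
    the caller anyway.
    """
    m = n * p
    sd = np.sqrt(max(n * p * (1.0 - p), 0.0))
    lo = max(0, int(np.floor(m - n_sd * sd)) - 2)
    hi = min(n, int(np.ceil(m + n_sd * sd)) + 2)
    k = np.arange(lo, hi + 1)
    if p <= 0.0:
        pm = np.zeros(k.size)
        if lo == 0:
            pm[0] = 1.0
        return lo, pm
    if p >= 1.0:
        pm = np.zeros(k.size)
        if hi == n:
            pm[-1] = 1.0
        return lo, pm
    logpm = (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + k * np.log(p)
        + (n - k) * np.log1p(-p)
    )
    return lo, np.exp(logpm)


def dtwf_transition_matrix(
    model: SelectionModel, no_fix: bool = True, k_max: int | None = None
) -> sparse.csr_matrix:
    """Sparse DTWF transition matrix over allele counts.

    With ``no_fix`` the fixation state (count two_N) is deleted and rows are
    renormalized, i.e. each generation is conditioned on non-fixation.
    ``k_max`` restricts the state space to counts 0..k_max (rows
    renormalized), which is all that is needed for the bottom-basin
    quasi-stationary solve and keeps strong-selection models tractable at
    full population size.
    """
    two_N = model.two_N
    top = two_N if no_fix else two_N + 1
    if k_max is not None:
        top = min(top, k_max + 1)
    f = np.arange(top) / two_N
    fp = _post_selection_mutation_freq(f, model.s_het, model.mu)
    rows, cols, vals = [], [], []
    for i in range(top):
        lo, pm = _binom_pmf_window(two_N, float(fp[i]))
        keep = slice(0, max(0, min(pm.size, top - lo)))
        pm = pm[keep]
        if pm.size == 0:
            raise RuntimeError(
                "state space truncation too aggressive: a row lost all its mass"
            )
        rows.append(np.full(pm.size, i))
        cols.append(np.arange(lo, lo + pm.size))
        vals.append(pm)
    P = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(top, top),
    )
    row_sums = np.asarray(P.sum(axis=1)).ravel()
    if np.any(row_sums <= 0):
        raise RuntimeError("transition matrix has an all-zero row after truncation")
    return (sparse.diags(1.0 / row_sums) @ P).tocsr()


def _stationary_direct(P: sparse.csr_matrix) -> np.ndarray:
    """Solve pi P = pi, sum(pi)=1 by replacing one equation with normalization."""
    m = P.shape[0]
    A = (P.T - sparse.identity(m, format="csr")).tolil()
    A[m - 1, :] = 1.0
    b = np.zeros(m)
    b[m - 1] = 1.0
    pi = splu(A.tocsc()).solve(b)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _stationary_forward(
    P: sparse.csr_matrix,
    start: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
) -> np.ndarray:
    """Iterate ``pi <- pi P`` from ``start`` until the L1 change drops below tol."""
    PT = P.T.tocsr()
    pi = start.copy()
    best = np.inf
    since_best = 0
    for _ in range(max_iter):
        nxt = PT @ pi
        nxt /= nxt.sum()
        change = np.abs(nxt - pi).sum()
        pi = nxt
        if change < tol:
            return pi
        # the per-iteration change bottoms out at the float64 noise floor;
        # accept once it has stopped improving at a level consistent with
        # round-off rather than genuine drift of the iterate
        if change < 0.99 * best:
            best = min(best, change)
            since_best = 0
        else:
            best = min(best, change)
            since_best += 1
            if since_best > 500 and best < 1e-9:
                return pi
    residual = float(np.abs(PT @ pi - pi).sum())
    raise RuntimeError(
        f"stationary iteration did not converge within {max_iter} iterations "
        f"(L1 residual {residual:.3e})"
    )


def compute_equilibrium_afs(
    model: SelectionModel,
    backend: str = "auto",
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
) -> FrequencyDistribution:
    """Equilibrium allele-frequency spectrum of the no-fixation DTWF chain.

    Parameters
    ----------
    model:
        Selection model; ``two_N`` must be at most 20,000.
    backend:
        ``"direct"`` solves the stationary linear system on the full
        no-fixation state space; ``"restricted"`` solves it on the bottom
        basin (counts <= two_N / 2), yielding the mutation-origin
        metastable equilibrium; ``"forward"`` iterates the distribution
        from the monomorphic state; ``"auto"`` (default) picks ``direct``
        when ``two_N * s_het <= 10`` and ``restricted`` otherwise (see the
        module docstring for why).
    """
    if backend == "auto":
        backend = "direct" if model.scaled_selection <= _BACKEND_SWITCH_NS else "restricted"
    # the size guard protects the solves that span the whole state space;
    # the restricted bottom-basin solve touches only ~14/s_het counts and
    # is checked against the same budget below
    if backend != "restricted" and model.two_N > MAX_TWO_N:
        raise ValueError(
            f"two_N={model.two_N} exceeds the tractable-state-space guard "
            f"({MAX_TWO_N}); rescale with desk_scale_model"
        )
    if backend == "restricted":
        support = int(np.ceil(28.0 / (2.0 * model.s_het))) + 50
        if min(model.two_N // 2, support) > MAX_TWO_N:
            raise ValueError(
                "restricted solve would exceed the tractable-state-space guard; "
                "rescale with desk_scale_model"
            )
    if model.mu == 0.0:
        # No mutational input: the monomorphic ancestral state is absorbing.
        probs = np.zeros(model.two_N)
        probs[0] = 1.0
        return FrequencyDistribution(probs=probs, model=model)
    if backend == "direct":
        P = dtwf_transition_matrix(model, no_fix=True)
        pi = _stationary_direct(P)
        residual = float(np.abs(P.T @ pi - pi).sum())
    elif backend == "restricted":
        # Mutation-origin metastable equilibrium: the underdominant scheme
        # has a potential maximum at f = 1/2, and for scaled selection
        # beyond the backend switch the probability that a mutant lineage
        # ever crosses it before loss is exponentially small.  The
        # quasi-stationary law of mutation-selection balance is computed as
        # the stationary law of the chain restricted (reflected by row
        # renormalization) to the bottom basin.  The basin equilibrium
        # decays at least as fast as exp(-2 s_het k) in the allele count k,
        # so the state space is further truncated where that bound falls
        # below 1e-24 relative; this keeps full-size populations tractable
        # under strong selection.
        support = int(np.ceil(28.0 / (2.0 * model.s_het))) + 50
        k_max = min(model.two_N // 2, support)
        P_low = dtwf_transition_matrix(model, no_fix=True, k_max=k_max)
        pi_low = _stationary_direct(P_low)
        pi = np.zeros(model.two_N)
        pi[: k_max + 1] = pi_low
        residual = float(np.abs(P_low.T @ pi_low - pi_low).sum())
    elif backend == "forward":
        P = dtwf_transition_matrix(model, no_fix=True)
        start = np.zeros(model.two_N)
        start[0] = 1.0
        pi = _stationary_forward(P, start, tol=tol, max_iter=max_iter)
        residual = float(np.abs(P.T @ pi - pi).sum())
    else:
        raise ValueError(f"unknown backend {backend!r}")
    if residual > 1e-8:
        raise RuntimeError(f"stationary solve residual too large: {residual:.3e}")
    return FrequencyDistribution(probs=pi / pi.sum(), model=model)


def diffusion_stationary_afs(
    model: SelectionModel,
    n_points: int | None = None,
    condition_on_loss: bool | str = "auto",
) -> FrequencyDistribution:
    """Diffusion-approximation stationary density on a frequency grid.

    The unconditioned density is Wright's formula for the underdominant
    scheme,

        phi(f) ~ exp(-2 two_N s_het f(1-f)) * [f(1-f)]^(2 two_N mu - 1).

    With ``condition_on_loss`` the density is weighted by the probability
    that an allele at frequency f is eventually lost rather than fixed,

        q(f) = int_f^1 exp(c x(1-x)) dx / int_0^1 exp(c x(1-x)) dx,

    with c = 2 two_N s_het, which removes the mass near fixation that
    underdominance would otherwise place there.  The default ``"auto"``
    mirrors the regime split of ``compute_equilibrium_afs``: for weak
    selection the discrete chain mixes across the interior and its
    stationary law tracks the unconditioned density (on minor-allele
    summaries, which are insensitive to the non-diffusive boundary layer
    that the per-generation non-fixation conditioning creates), while for
    strong selection the chain's mutation-origin equilibrium tracks the
    loss-conditioned density.

    The density is integrated over cells centred on the DTWF count grid
    (f_k = k / two_N by default) so that the integrable boundary
    singularities are represented with the same resolution as the discrete
    chain, and the result is returned as a FrequencyDistribution on that
    grid.
    """
    theta = 2.0 * model.two_N * model.mu
    if theta <= 0.0:
        raise ValueError("diffusion density requires 2 * two_N * mu > 0")
    grid_n = model.two_N if n_points is None else int(n_points)
    if grid_n < 4:
        raise ValueError("need at least 4 grid points")
    if condition_on_loss == "auto":
        condition_on_loss = model.scaled_selection > _BACKEND_SWITCH_NS
    c = 2.0 * model.two_N * model.s_het

    # Cell boundaries straddling f_k = k / grid_n for k = 0 .. grid_n - 1;
    # the first cell absorbs [0, 1/(2 grid_n)) and the last stops short of
    # fixation, mirroring the no-fixation state space.
    edges = (np.arange(grid_n + 1) - 0.5) / grid_n
    edges[0] = 0.0
    edges[-1] = 1.0 - 0.5 / grid_n

    if condition_on_loss and c > 0:
        # loss probability q(f) = int_f^1 e^{c x(1-x)} dx / int_0^1, the
        # diffusion analogue of the chain's non-fixation conditioning
        x_q = np.linspace(0.0, 1.0, 8193)
        g = np.exp(c * x_q * (1.0 - x_q) - c / 4.0)
        G = np.concatenate([[0.0], np.cumsum(0.5 * (g[1:] + g[:-1]) * np.diff(x_q))])

        def _loss_prob(fm: np.ndarray) -> np.ndarray:
            tail = np.interp(fm, x_q, G)
            return (G[-1] - tail) / G[-1]

    elif condition_on_loss:

        def _loss_prob(fm: np.ndarray) -> np.ndarray:
            return 1.0 - fm

    else:

        def _loss_prob(fm: np.ndarray) -> np.ndarray:
            return np.ones_like(fm)

    def _smooth_left(f: np.ndarray) -> np.ndarray:
        # integrand divided by the f^(theta-1) singular factor
        out = np.exp(-c * f * (1.0 - f) + (theta - 1.0) * np.log1p(-f))
        return out * _loss_prob(f)

    def _smooth_right(f: np.ndarray) -> np.ndarray:
        # integrand divided by the (1-f)^(theta-1) singular factor
        out = np.exp(-c * f * (1.0 - f) + (theta - 1.0) * np.log(np.maximum(f, 1e-300)))
        return out * _loss_prob(f)

    def _cell_mass(a: float, b: float) -> float:
        """Integrate phi over [a, b] exactly absorbing the boundary singularity.

        For cells in the left half substitute u = f^theta so that
        int f^(theta-1) g(f) df = (1/theta) int g(u^(1/theta)) du; the mass of
        the integrable singularity then lives on a regular u grid even when
        the corresponding f underflows.  Right-half cells use the mirrored
        substitution v = (1-f)^theta.
        """
        if b <= a:
            return 0.0
        n_sub = 48
        mid_f = 0.5 * (a + b)
        if mid_f <= 0.5:
            u = np.linspace(a**theta, b**theta, n_sub + 1)
            um = 0.5 * (u[1:] + u[:-1])
            with np.errstate(under="ignore"):
                f = um ** (1.0 / theta)
            vals = _smooth_left(f)
            return float((vals * np.diff(u)).sum() / theta)
        u = np.linspace((1.0 - b) ** theta, (1.0 - a) ** theta, n_sub + 1)
        um = 0.5 * (u[1:] + u[:-1])
        with np.errstate(under="ignore"):
            f = 1.0 - um ** (1.0 / theta)
        vals = _smooth_right(f)
        return float((vals * np.diff(u)).sum() / theta)

    masses = np.array([_cell_mass(edges[k], edges[k + 1]) for k in range(grid_n)])
    total = masses.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError(
            "diffusion density is not integrable for these parameters "
            f"(theta={theta}, c={c})"
        )
    if grid_n == model.two_N:
        grid_model = model
    else:
        if grid_n % 2:
            raise ValueError("n_points must be even (count-grid convention)")
        # keep the drift-scaled parameters of the input model on the new grid
        scale = model.two_N / grid_n
        grid_model = SelectionModel(
            min(1.0, model.s_het * scale), model.mu * scale, grid_n
        )
    return FrequencyDistribution(probs=masses / total, model=grid_model)


def closed_form_balance(mu: float, s_het: float) -> float:
    """Deterministic mutation-selection balance frequency mu / s_het.

    Valid only when selection dominates mutation; guarded at
    ``s_het >= 100 * mu``.
    """
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    if mu == 0.0:
        if s_het <= 0:
            raise ValueError("s_het must be positive")
        return 0.0
    if s_het < 100.0 * mu:
        raise ValueError(
            "weak-selection regime: closed-form balance requires s_het >= 100 * mu"
        )
    return mu / s_het


def simulate_trajectories(
    model: SelectionModel,
    generations: int,
    n_reps: int,
    init_count: int = 1,
    seed: int | np.random.Generator = 0,
) -> TrajectoryEnsemble:
    """Binomial Wright-Fisher trajectories without recurrent mutation.

    Each generation applies the heterozygote-selection expected-frequency
    map and then binomial resampling; counts 0 and two_N are absorbing.
    All replicates are advanced together one generation at a time, so draws
    are consumed generation-major from a single seeded generator.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if not 1 <= init_count <= model.two_N - 1:
        raise ValueError(
            f"init_count must be in [1, two_N-1]={model.two_N - 1}, got {init_count}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    two_N = model.two_N
    freqs = np.empty((n_reps, generations + 1))
    freqs[:, 0] = init_count / two_N
    counts = np.full(n_reps, init_count, dtype=np.int64)
    for t in range(1, generations + 1):
        f = counts / two_N
        segregating = (counts > 0) & (counts < two_N)
        fp = _post_selection_mutation_freq(f, model.s_het, 0.0)
        counts = np.where(segregating, rng.binomial(two_N, np.clip(fp, 0.0, 1.0)), counts)
        freqs[:, t] = counts / two_N
    return TrajectoryEnsemble(frequencies=freqs, model=model)


@dataclass
class SelectionGrid:
    """Spectra along a strictly increasing grid of s_het values.

    The grid values are on the *reference* population scale; each spectrum
    may be computed on a rescaled desk-size chain (see ``build``).
    """

    grid: np.ndarray
    spectra: list[FrequencyDistribution]
    _log10: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.size == 0:
            raise ValueError("empty selection grid")
        if self.grid.size != len(self.spectra):
            raise ValueError("grid and spectra length mismatch")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        self._log10 = np.log10(self.grid)

    @classmethod
    def build(
        cls,
        s_values: Sequence[float] | None = None,
        grid_min: float = 1e-7,
        grid_max: float = 0.05,
        grid_size: int = 50,
        mu: float = DEFAULT_MU,
        two_N_ref: int = REFERENCE_TWO_N,
        two_N: int = 2_000,
    ) -> "SelectionGrid":
        """Compute spectra on a log-spaced s_het grid.

        Defaults mirror the study design: 50 values from 1e-7 to 0.05,
        evenly spaced on the log scale, for a reference population of
        20,000 diploids with mu = 1.25e-8, computed on a desk-scale chain
        of two_N = 2,000 with the drift-scaled parameters preserved.
        """
        if s_values is None:
            s_values = np.geomspace(grid_min, grid_max, grid_size)
        s_values = np.asarray(s_values, dtype=float)
        # Per-point rescaling: strong selection confines the equilibrium to
        # a small bottom basin, so those spectra are solved at (or near)
        # full reference size; only weakly selected points, whose solve
        # spans the whole chain, are rescaled down to the desk size.  The
        # basin size is ~14/s_chain counts, and the solve budget is the
        # desk chain size.
        budget = two_N
        spectra = []
        for s in s_values:
            r_needed = 14.0 / (max(s, 1e-300) * (budget - 50)) if s > 0 else np.inf
            r = float(np.clip(r_needed, 1.0, two_N_ref / two_N))
            two_N_c = max(two_N, int(round(two_N_ref / r / 2)) * 2)
            scale = two_N_ref / two_N_c
            m = SelectionModel(min(1.0, s * scale), mu * scale, two_N_c)
            spectra.append(compute_equilibrium_afs(m))
        return cls(grid=s_values, spectra=spectra)

    def nearest_index(self, s_het: float) -> int:
        if s_het <= 0:
            raise ValueError("s_het must be positive")
        d = np.abs(self._log10 - np.log10(s_het))
        # ties broken toward the smaller grid value: argmin takes the first
        # minimum, and the grid is increasing.
        return int(np.argmin(d))

    def nearest_indices(self, s_het: np.ndarray) -> np.ndarray:
        s_het = np.asarray(s_het, dtype=float)
        if np.any(s_het <= 0):
            raise ValueError("s_het values must be positive")
        d = np.abs(self._log10[None, :] - np.log10(s_het)[:, None])
        return np.argmin(d, axis=1)

    def mean_heterozygosities(self) -> np.ndarray:
        return np.array([sp.mean_heterozygosity() for sp in self.spectra])

    def mean_frequencies(self) -> np.ndarray:
        return np.array([sp.mean_frequency() for sp in self.spectra])


def nearest_spectrum(grid: SelectionGrid, s_het: float) -> FrequencyDistribution:
    """Spectrum whose grid value is closest to s_het on the log10 scale."""
    return grid.spectra[grid.nearest_index(s_het)]


_GRID_CACHE: dict[tuple, SelectionGrid] = {}


def default_selection_grid(
    grid_min: float = 1e-7,
    grid_max: float = 0.05,
    grid_size: int = 50,
    mu: float = DEFAULT_MU,
    two_N: int = 2_000,
) -> SelectionGrid:
    """The study-design selection grid, built once per process and cached."""
    key = (grid_min, grid_max, grid_size, mu, two_N)
    if key not in _GRID_CACHE:
        _GRID_CACHE[key] = SelectionGrid.build(
            grid_min=grid_min, grid_max=grid_max, grid_size=grid_size, mu=mu, two_N=two_N
        )
    return _GRID_CACHE[key]
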