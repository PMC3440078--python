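"""Block MCMC for the structured additive Poisson model.

The posterior is sampled by Metropolis-within-Gibbs over parameter blocks:
fixed effects (intercept, day-of-week, dust-storm index, PM10), the two
P-spline coefficient blocks, the unstructured and structured spatial effects,
and finally all variance parameters.  Gaussian blocks use a
Metropolis-Hastings step with an iteratively-weighted-least-squares (IWLS)
proposal: the Poisson log-likelihood is expanded to second order around the
current block value, giving a Gaussian proposal whose precision is the
working information plus the block's prior precision; the accept/reject step
makes the exact posterior the stationary distribution.  Variances have
conjugate inverse-gamma full conditionals under IG(a, b) hyperpriors
(default a = b = 0.001).

Optionally, per-observation multiplicative gamma effects with fixed shape
``nu`` turn the observation model into Poisson-gamma (negative binomial),
giving district-level overdispersion Var(Y) = mu (1 + mu / nu); these latent
effects have conjugate gamma full conditionals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .design import DesignBundle, LINEAR_COLUMNS
from .smoothers import bspline_basis
from .spatial import car_precision

__all__ = [
    "ModelState",
    "PosteriorDraws",
    "retained_count",
    "update_variance",
    "update_gaussian_block",
    "run_chain",
]

logger = logging.getLogger(__name__)

_ETA_CLIP = 80.0  # |log mu| beyond this is treated as divergent


def retained_count(total: int, burnin: int, thin: int) -> int:
    """Number of retained draws: floor((total - burnin) / thin), > 0."""
    if burnin < 0 or thin < 1 or total <= burnin:
        raise ValueError(
            f"invalid schedule total={total}, burnin={burnin}, thin={thin}"
        )
    kept = (total - burnin) // thin
    if kept < 1:
        raise ValueError("schedule retains no draws")
    return kept


def update_variance(
    coefficients: np.ndarray,
    structure: np.ndarray,
    a: float,
    b: float,
    rng: np.random.Generator,
    rank: int | None = None,
) -> float:
    """Conjugate inverse-gamma draw for a prior variance.

    The full conditional of the variance of a Gaussian (intrinsic) prior with
    structure matrix K is IG(a + rank(K)/2, b + coeff' K coeff / 2).
    """
    if a <= 0 or b <= 0:
        raise ValueError("inverse-gamma hyperparameters must be positive")
    theta = np.asarray(coefficients, dtype=float)
    K = np.asarray(structure, dtype=float)
    if rank is None:
        rank = int(np.linalg.matrix_rank(K))
    if rank == 0:
        raise ValueError("structure matrix has rank zero")
    shape = a + rank / 2.0
    scale = b + 0.5 * float(theta @ K @ theta)
    return scale / rng.gamma(shape)


# ---------------------------------------------------------------------------
# design blocks: each knows how to expand coefficients to the observation
# vector and how to form the IWLS cross-products without materializing a
# full n x m matrix where the covariate only varies by day or district


class _DenseBlock:
    def __init__(self, X: np.ndarray):
        self.X = X
        self.dim = X.shape[1]

    def expand(self, theta):
        return self.X @ theta

    def xtv(self, v):
        return self.X.T @ v

    def gram(self, w):
        return self.X.T @ (w[:, None] * self.X)


class _DayBlock:
    """Day-level basis B (T x m) replicated across districts."""

    def __init__(self, B: np.ndarray, day_index: np.ndarray):
        self.B = B
        self.day_index = day_index
        self.T = B.shape[0]
        self.dim = B.shape[1]

    def expand(self, theta):
        return (self.B @ theta)[self.day_index]

    def xtv(self, v):
        return self.B.T @ np.bincount(self.day_index, weights=v, minlength=self.T)

    def gram(self, w):
        wd = np.bincount(self.day_index, weights=w, minlength=self.T)
        return self.B.T @ (wd[:, None] * self.B)


class _GroupBlock:
    """District indicator block (one effect per district)."""

    def __init__(self, district_index: np.ndarray, S: int):
        self.idx = district_index
        self.dim = S

    def expand(self, theta):
        return theta[self.idx]

    def xtv(self, v):
        return np.bincount(self.idx, weights=v, minlength=self.dim)

    def gram(self, w):
        return np.diag(np.bincount(self.idx, weights=w, minlength=self.dim))


def _find_mode(block, theta, eta_rest, y, prior_prec):
    """Mode of a block's full conditional by iterated IWLS (Newton on a
    concave log-target); returns (mode, Cholesky of the precision there)."""
    mean = np.asarray(theta, dtype=float)
    L = None
    for _ in range(50):
        eta = eta_rest + block.expand(mean)
        if np.abs(eta).max() > _ETA_CLIP:
            return None
        mu = np.exp(eta)
        bvec = block.xtv(mu * block.expand(mean) + (y - mu))
        P = block.gram(mu) + prior_prec
        try:
            L = np.linalg.cholesky(P)
        except np.linalg.LinAlgError:
            return None
        new_mean = np.linalg.solve(P, bvec)
        delta = float(np.max(np.abs(new_mean - mean)))
        mean = new_mean
        if delta < 1e-9 * (1.0 + float(np.max(np.abs(mean)))):
            break
    return mean, L


def _gaussian_logpdf_chol(x, mean, chol_prec):
    r = chol_prec.T @ (x - mean)
    return float(np.log(np.diag(chol_prec)).sum() - 0.5 * r @ r)


def update_gaussian_block(
    block,
    theta: np.ndarray,
    eta_rest: np.ndarray,
    y: np.ndarray,
    prior_prec: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """One IWLS Metropolis-Hastings update of a Gaussian coefficient block.

    Parameters
    ----------
    block
        Design block with ``expand``/``xtv``/``gram``.
    theta
        Current block coefficients.
    eta_rest
        Linear predictor contribution of everything else, including the
        offset (and any latent overdispersion effects).
    y
        Observed counts.
    prior_prec
        Block prior precision matrix (possibly rank-deficient, e.g. RW2 or
        intrinsic CAR divided by its variance).

    Returns
    -------
    (new_theta, accepted)

    Notes
    -----
    The IWLS step ``m <- (X'WX + P0)^-1 X'W z`` (W = mu, working response
    ``z = eta + (y - mu)/mu``) is iterated to convergence, i.e. to the mode
    of the block's full conditional, and the proposal is the Gaussian with
    that mean and the working precision there.  Because the mode depends
    only on the conditioning state, the forward and reverse proposal
    distributions coincide and the Hastings correction reduces to density
    ratios under one Gaussian.
    """

    def log_target(th):
        eta = eta_rest + block.expand(th)
        if np.abs(eta).max() > _ETA_CLIP:
            return -np.inf
        return float(y @ eta - np.exp(eta).sum() - 0.5 * th @ prior_prec @ th)

    found = _find_mode(block, theta, eta_rest, y, prior_prec)
    if found is None:
        logger.warning("non-finite working weights; block update rejected")
        return theta, False
    mean, L = found

    z = rng.standard_normal(block.dim)
    prop = mean + np.linalg.solve(L.T, z)

    log_alpha = (
        log_target(prop) - log_target(theta)
        + _gaussian_logpdf_chol(theta, mean, L)
        - _gaussian_logpdf_chol(prop, mean, L)
    )
    if not np.isfinite(log_alpha):
        return theta, False
    if np.log(rng.uniform()) < log_alpha:
        return prop, True
    return theta, False


# ---------------------------------------------------------------------------


@dataclass
class ModelState:
    """All unknowns of the model at one MCMC iteration."""

    fixed: np.ndarray          # (11,) alpha, delta (6), beta (3), gamma
    spline_tp: np.ndarray      # (m_tp,) temperature smooth coefficients
    spline_t: np.ndarray       # (m_t,) calendar-trend coefficients
    u: np.ndarray              # (S,) unstructured spatial effects
    eta: np.ndarray            # (S,) structured (CAR) spatial effects
    tau2_tp: float
    tau2_t: float
    sigma2_u: float
    sigma2_s: float
    log_disp: np.ndarray | None = None  # (n,) latent log gamma effects


@dataclass
class PosteriorDraws:
    """Retained MCMC samples for every parameter block."""

    params: dict[str, np.ndarray]
    total: int
    burnin: int
    thin: int
    seed: int
    districts: list = field(default_factory=list)
    acceptance: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.params[name]

    @property
    def n_draws(self) -> int:
        return retained_count(self.total, self.burnin, self.thin)

    def save(self, path) -> None:
        """Write draws plus schedule metadata to an .npz archive."""
        meta = dict(total=self.total, burnin=self.burnin, thin=self.thin,
                    seed=self.seed)
        np.savez(
            path,
            _districts=np.array([str(d) for d in self.districts]),
            _meta=np.array([meta["total"], meta["burnin"], meta["thin"],
                            meta["seed"]], dtype=np.int64),
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        with np.load(path, allow_pickle=False) as z:
            meta = z["_meta"]
            params = {k: z[k] for k in z.files if not k.startswith("_")}
            districts = [str(d) for d in z["_districts"]]
        return cls(params=params, total=int(meta[0]), burnin=int(meta[1]),
                   thin=int(meta[2]), seed=int(meta[3]), districts=districts)

    def to_inference_data(self):
        """Package the draws as an :mod:`arviz` InferenceData (one chain)."""
        import arviz as az

        return az.from_dict({k: v[None, ...] for k, v in self.params.items()})


def run_chain(
    bundle: DesignBundle,
    iterations: int = 22000,
    burnin: int = 2000,
    thin: int = 20,
    seed: int = 20120315,
    m_temperature: int = 10,
    m_time: int = 20,
    ig_a: float = 0.001,
    ig_b: float = 0.001,
    adjacency=None,
    dispersion_nu: float | None = None,
    fixed_prior_var: float = 1e6,
) -> PosteriorDraws:
    """Run the block sampler and return the retained draws.

    Parameters
    ----------
    bundle
        Assembled design (see :func:`adstar.design.build_design`).
    iterations, burnin, thin
        Sampling schedule; the default (22000, 2000, 20) retains 1000 draws.
    seed
        Seed of the single pseudo-random stream; identical inputs and seed
        give bit-identical draws.
    m_temperature, m_time
        Number of B-spline basis functions for f(TP) and f(T).
    ig_a, ig_b
        IG(a, b) hyperprior for every variance parameter.
    adjacency
        ``networkx.Graph`` on the district identifiers of ``bundle``.
    dispersion_nu
        If given, Poisson-gamma overdispersion with fixed gamma shape nu;
        ``None`` fits a plain Poisson model.
    """
    import networkx as nx

    kept = retained_count(iterations, burnin, thin)
    rng = np.random.Generator(np.random.PCG64(seed))

    y = bundle.y
    offset = bundle.offset
    n = bundle.n_obs
    S = bundle.n_districts

    if adjacency is None:
        raise ValueError("an adjacency graph over the districts is required")
    missing = [d for d in bundle.districts if d not in adjacency]
    if missing:
        raise ValueError(f"districts missing from adjacency graph: {missing}")
    graph = nx.Graph()
    graph.add_nodes_from(bundle.districts)
    graph.add_edges_from(
        (a, b) for a, b in adjacency.edges if a in graph and b in graph
    )
    Q = car_precision(graph)

    basis_tp = bspline_basis(bundle.temperature, m_temperature)
    basis_t = bspline_basis(np.arange(bundle.n_days, dtype=float), m_time)

    # eta precedes u: the two district blocks are likelihood-identified only
    # through their sum, so the structured (CAR) effect is given first claim
    # on the spatial signal and u keeps the spatially unstructured remainder
    blocks = {
        "fixed": _DenseBlock(bundle.X),
        "spline_tp": _DayBlock(basis_tp.basis, bundle.day_index),
        "spline_t": _DayBlock(basis_t.basis, bundle.day_index),
        "eta": _GroupBlock(bundle.district_index, S),
        "u": _GroupBlock(bundle.district_index, S),
    }
    K_tp, K_t = basis_tp.penalty, basis_t.penalty
    I_fixed = np.eye(len(LINEAR_COLUMNS)) / fixed_prior_var

    state = ModelState(
        fixed=np.zeros(len(LINEAR_COLUMNS)),
        spline_tp=np.zeros(m_temperature),
        spline_t=np.zeros(m_time),
        u=np.zeros(S),
        eta=np.zeros(S),
        tau2_tp=0.01, tau2_t=0.01, sigma2_u=0.01, sigma2_s=0.1,
        log_disp=np.zeros(n) if dispersion_nu is not None else None,
    )
    # start the intercept near the crude log rate
    state.fixed[0] = float(np.log(y.mean() + 0.5) - offset.mean())

    contrib = {name: blocks[name].expand(getattr(state, name))
               for name in blocks}

    def eta_rest_for(name):
        rest = offset.copy()
        for other, v in contrib.items():
            if other != name:
                rest += v
        if state.log_disp is not None:
            rest += state.log_disp
        return rest

    rank_tp = m_temperature - 2
    rank_t = m_time - 2
    rank_q = S - 1

    # posterior-mode initialization by IWLS backfitting: start every block
    # at its conditional mode so the Gaussian-at-mode proposals are accepted
    # from the first iteration (a far-from-mode start would be rejected
    # almost surely under the exact Hastings correction)
    block_priors = {
        "fixed": lambda: I_fixed,
        "spline_tp": lambda: K_tp / state.tau2_tp,
        "spline_t": lambda: K_t / state.tau2_t,
        "u": lambda: np.eye(S) / state.sigma2_u,
        "eta": lambda: Q / state.sigma2_s,
    }
    var_specs = (
        ("tau2_tp", "spline_tp", K_tp, rank_tp),
        ("tau2_t", "spline_t", K_t, rank_t),
        ("sigma2_u", "u", np.eye(S), S),
        ("sigma2_s", "eta", Q, rank_q),
    )
    for _ in range(4):
        for name in blocks:
            found = _find_mode(blocks[name], getattr(state, name),
                               eta_rest_for(name), y, block_priors[name]())
            if found is not None:
                setattr(state, name, found[0])
                contrib[name] = blocks[name].expand(found[0])
        for var_name, coef_name, K, rank in var_specs:
            coef = getattr(state, coef_name)
            # conditional posterior mean of the variance
            setattr(state, var_name,
                    (ig_b + 0.5 * float(coef @ K @ coef))
                    / max(ig_a + rank / 2.0 - 1.0, 0.5))

    draws = {
        "alpha": np.empty(kept),
        "dow": np.empty((kept, 6)),
        "dsi": np.empty((kept, 3)),
        "gamma": np.empty(kept),
        "spline_tp": np.empty((kept, m_temperature)),
        "spline_t": np.empty((kept, m_time)),
        "u": np.empty((kept, S)),
        "eta": np.empty((kept, S)),
        "tau2_tp": np.empty(kept),
        "tau2_t": np.empty(kept),
        "sigma2_u": np.empty(kept),
        "sigma2_s": np.empty(kept),
        "log_post": np.empty(kept),
    }
    accept = {name: 0 for name in blocks}

    def log_posterior():
        eta_full = offset.copy()
        for v in contrib.values():
            eta_full += v
        if state.log_disp is not None:
            eta_full += state.log_disp
        lp = float(y @ eta_full - np.exp(eta_full).sum())
        lp -= 0.5 * state.fixed @ I_fixed @ state.fixed
        lp -= 0.5 * state.spline_tp @ K_tp @ state.spline_tp / state.tau2_tp
        lp -= 0.5 * state.spline_t @ K_t @ state.spline_t / state.tau2_t
        lp -= 0.5 * state.u @ state.u / state.sigma2_u
        lp -= 0.5 * state.eta @ Q @ state.eta / state.sigma2_s
        return lp

    kept_i = 0
    for it in range(iterations):
        # --- Gaussian blocks, IWLS-MH ---------------------------------
        for name, prior in (
            ("fixed", I_fixed),
            ("spline_tp", K_tp / state.tau2_tp),
            ("spline_t", K_t / state.tau2_t),
            ("eta", Q / state.sigma2_s),
            ("u", np.eye(S) / state.sigma2_u),
        ):
            theta = getattr(state, name)
            new, ok = update_gaussian_block(
                blocks[name], theta, eta_rest_for(name), y, prior, rng
            )
            if ok:
                setattr(state, name, new)
                contrib[name] = blocks[name].expand(new)
                accept[name] += 1

        # --- identifiability: centre smooths and the CAR effect -------
        for name, basis in (("spline_tp", basis_tp), ("spline_t", basis_t)):
            th = getattr(state, name)
            c = float((basis.basis @ th).mean())
            if c != 0.0:
                th = th - c  # rows sum to 1, so the fit shifts by -c
                setattr(state, name, th)
                contrib[name] = blocks[name].expand(th)
                state.fixed[0] += c
        c = float(state.eta.mean())
        if c != 0.0:
            state.eta = state.eta - c
            contrib["eta"] = blocks["eta"].expand(state.eta)
            state.fixed[0] += c
        contrib["fixed"] = blocks["fixed"].expand(state.fixed)

        # --- latent overdispersion effects (conjugate) -----------------
        if dispersion_nu is not None:
            base = offset.copy()
            for v in contrib.values():
                base += v
            mu0 = np.exp(np.clip(base, -_ETA_CLIP, _ETA_CLIP))
            e = rng.gamma(dispersion_nu + y) / (dispersion_nu + mu0)
            state.log_disp = np.log(e)

        # --- variances (conjugate inverse gamma) -----------------------
        state.tau2_tp = update_variance(state.spline_tp, K_tp, ig_a, ig_b,
                                        rng, rank=rank_tp)
        state.tau2_t = update_variance(state.spline_t, K_t, ig_a, ig_b,
                                       rng, rank=rank_t)
        state.sigma2_u = update_variance(state.u, np.eye(S), ig_a, ig_b,
                                         rng, rank=S)
        state.sigma2_s = update_variance(state.eta, Q, ig_a, ig_b,
                                         rng, rank=rank_q)

        # --- store ------------------------------------------------------
        if it >= burnin and (it - burnin) % thin == thin - 1:
            lp = log_posterior()
            if not np.isfinite(lp):
                raise FloatingPointError(
                    f"divergent state at iteration {it}: log-posterior {lp}; "
                    f"fixed={state.fixed}"
                )
            draws["alpha"][kept_i] = state.fixed[0]
            draws["dow"][kept_i] = state.fixed[1:7]
            draws["dsi"][kept_i] = state.fixed[7:10]
            draws["gamma"][kept_i] = state.fixed[10]
            draws["spline_tp"][kept_i] = state.spline_tp
            draws["spline_t"][kept_i] = state.spline_t
            draws["u"][kept_i] = state.u
            draws["eta"][kept_i] = state.eta
            draws["tau2_tp"][kept_i] = state.tau2_tp
            draws["tau2_t"][kept_i] = state.tau2_t
            draws["sigma2_u"][kept_i] = state.sigma2_u
            draws["sigma2_s"][kept_i] = state.sigma2_s
            draws["log_post"][kept_i] = lp
            kept_i += 1

    rates = {k: v / iterations for k, v in accept.items()}
    logger.info("acceptance rates: %s", rates)
    return PosteriorDraws(
        params=draws, total=iterations, burnin=burnin, thin=thin, seed=seed,
        districts=list(bundle.districts), acceptance=rates,
    )
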