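"""Maximum-likelihood fitting by simulated annealing.

The Bernoulli log-likelihood of a niche model is multimodal (the niche
axis is identifiable only up to reflection, and species can swap
positions), so fitting uses Kirkpatrick-style simulated annealing:
single-coordinate Gaussian proposals reflected at the parameter bounds,
Metropolis acceptance exp(ΔlnL/T), geometric cooling, and several
independent restarts of which the best is kept.

The first restart warm-starts from a trophic ordering of the web (n from
the normalized trophic-sort rank, c at the mean prey position, r at 0.2);
later restarts start uniform-random inside the bounds.  Coordinates
pinned by the data (producer c and r, specialist r) are never proposed.

An exhaustive :func:`grid_search_oracle` over a parameter lattice is
provided for verifying the annealer on tiny problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pnm_core import (
    A_DEFAULT,
    P_FLOOR,
    R_FLOOR,
    R_MAX,
    ConstraintMask,
    ParamSet,
    aic,
    log_likelihood,
    probability_matrix,
)
from .variants import ModelSpec, allometric_niche, expand_params
from .web_data import FoodWeb

__all__ = ["AnnealConfig", "FitResult", "fit", "propose", "grid_search_oracle"]

# Bounds for global coupling coefficients; coupled per-species values are
# clamped into the model bounds afterwards, so mildly out-of-range
# intermediates are harmless.
_GLOBAL_BOUNDS = {
    ("c_of_n", "c0"): (-1.0, 1.0),
    ("c_of_n", "c1"): (-2.0, 2.0),
    ("c_and_r_of_n", "c0"): (-1.0, 1.0),
    ("c_and_r_of_n", "c1"): (-2.0, 2.0),
    ("c_and_r_of_n", "r0"): (-1.0, 1.0),
    ("c_and_r_of_n", "r1"): (-2.0, 2.0),
    ("r_of_n", "r0"): (-1.0, 1.0),
    ("r_of_n", "r1"): (-2.0, 2.0),
    ("r_of_c", "r0"): (R_FLOOR, R_MAX),
    ("r_of_c", "r1"): (-5.0, 5.0),
}


@dataclass
class AnnealConfig:
    """Annealing schedule.

    Defaults are sized for an ~90-parameter problem: geometric cooling
    T_k = T0·cooling^k over `stages` stages, `steps_per_stage` proposals
    per stage (50 per free coordinate when left at None), and `restarts`
    independent runs.  Proposals are a mixture: with probability
    `p_uniform` a uniform redraw of one coordinate, with `p_swap` a swap
    of two species' whole parameter blocks (the move that lets the
    annealer reorder the axis), otherwise a reflected Gaussian step on
    one coordinate.
    """

    t0: float = 1.0
    cooling: float = 0.95
    stages: int = 200
    steps_per_stage: int | None = None
    restarts: int = 5
    step_sigma: float = 0.1
    p_uniform: float = 0.10
    p_swap: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling must lie in (0, 1)")
        if self.stages < 1 or self.restarts < 1:
            raise ValueError("stages and restarts must be >= 1")
        if self.steps_per_stage is not None and self.steps_per_stage < 1:
            raise ValueError("steps_per_stage must be >= 1")
        if self.step_sigma < 0:
            raise ValueError("step_sigma must be non-negative")
        if self.p_uniform < 0 or self.p_swap < 0 or self.p_uniform + self.p_swap > 1:
            raise ValueError("proposal mixture weights must be in [0, 1]")


@dataclass
class FitResult:
    """Best parameter set found, with its likelihood and AIC."""

    params: ParamSet
    lnl: float
    k: int
    aic: float
    trace: np.ndarray          # best lnL after each stage (best restart)
    seed_used: int
    model: str
    config: AnnealConfig = field(repr=False, default=None)


def _layout(spec: ModelSpec, S: int, mask: ConstraintMask):
    """Per-coordinate bounds and the indices the annealer may move."""
    lo = np.empty(spec.n_params(S))
    hi = np.empty_like(lo)
    optimizable = np.ones(lo.shape[0], dtype=bool)
    for b, name in enumerate(spec.blocks):
        sl = slice(b * S, (b + 1) * S)
        if name in ("n", "c"):
            lo[sl], hi[sl] = 0.0, 1.0
        else:
            lo[sl], hi[sl] = R_FLOOR, R_MAX
        if name == "c":
            optimizable[sl] = ~mask.producer
        elif name == "r":
            optimizable[sl] = ~(mask.producer | mask.specialist)
    off = len(spec.blocks) * S
    for g, gname in enumerate(spec.global_names):
        lo[off + g], hi[off + g] = _GLOBAL_BOUNDS[(spec.name, gname)]
    return lo, hi, np.nonzero(optimizable)[0]


def _trophic_rank(web: FoodWeb) -> np.ndarray:
    """Normalized trophic-sort rank in [0, 1]; ties broken by prey count.

    Heights come from a damped fixed-point of h_i = 1 + mean prey height
    (robust to loops/cannibalism), which orders producers low and apex
    consumers high.
    """
    A = web.A.astype(float)
    R = A.sum(axis=1)
    h = np.ones(web.S)
    consumers = R > 0
    for _ in range(50):
        mean_prey = np.where(consumers, (A @ h) / np.maximum(R, 1), 0.0)
        h = 0.5 * h + 0.5 * (1.0 + mean_prey)
    order = np.lexsort((R, h))
    rank = np.empty(web.S)
    rank[order] = np.arange(web.S)
    return rank / max(web.S - 1, 1)


def _warm_start(
    web: FoodWeb,
    spec: ModelSpec,
    mask: ConstraintMask,
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray:
    n0 = _trophic_rank(web)
    R = web.A.sum(axis=1)
    c0 = np.where(
        R > 0, web.A @ n0 / np.maximum(R, 1), 0.0
    )
    r0 = np.full(web.S, 0.2)
    state = np.empty(spec.n_params(web.S))
    values = {"n": n0, "c": np.clip(c0, 0, 1), "r": r0}
    for b, name in enumerate(spec.blocks):
        state[b * web.S : (b + 1) * web.S] = values[name]
    guesses = {"c0": 0.0, "c1": 0.75, "r0": 0.05, "r1": 0.5}
    if spec.name == "r_of_c":
        guesses["r1"] = 1.0
    off = len(spec.blocks) * web.S
    for g, gname in enumerate(spec.global_names):
        state[off + g] = np.clip(guesses[gname], lo[off + g], hi[off + g])
    return state


def propose(
    state: np.ndarray,
    config: AnnealConfig,
    rng: np.random.Generator,
    optimizable: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
) -> np.ndarray:
    """Perturb one uniformly chosen free coordinate, reflecting at bounds.

    The perturbation is Normal(0, step_sigma·(hi−lo)) on the chosen
    coordinate; all others are unchanged.
    """
    cand = state.copy()
    i = optimizable[rng.integers(optimizable.shape[0])]
    x = cand[i] + rng.normal(0.0, config.step_sigma * (hi[i] - lo[i]))
    span = hi[i] - lo[i]
    while x < lo[i] or x > hi[i]:
        if x < lo[i]:
            x = lo[i] + (lo[i] - x)
        if x > hi[i]:
            x = hi[i] - (x - hi[i])
        if span == 0:
            x = lo[i]
            break
    cand[i] = x
    return cand


class _Objective:
    """Incremental Bernoulli log-likelihood over packed states.

    A single-coordinate proposal changes at most one row (that species'
    c or r, and any range coupled to them) and one column (its n) of the
    probability matrix, so the likelihood delta is computed from S-length
    slices instead of the full S×S matrix.  Global-coefficient proposals
    fall back to a full re-evaluation.
    """

    def __init__(self, spec: ModelSpec, web: FoodWeb, mask: ConstraintMask,
                 n_allo: np.ndarray | None, a: float = A_DEFAULT):
        self.spec = spec
        self.S = web.S
        self.A1 = web.A == 1
        self.mask = mask
        self.n_allo = n_allo
        self.a = a
        # coordinate index -> (block name or "global", species index or global pos)
        self.coord_kind: list[tuple[str, int]] = []
        for name in spec.blocks:
            self.coord_kind += [(name, s) for s in range(self.S)]
        self.coord_kind += [("global", g) for g in range(len(spec.global_names))]
        self._pending = None

    # -- expansion helpers -------------------------------------------------
    def _expand(self, state: np.ndarray):
        p = expand_params(self.spec, state, self.S, n_allometric=self.n_allo,
                          a=self.a)
        r_eff = p.r.copy()
        r_eff[self.mask.specialist] = R_FLOOR
        r_eff[self.mask.producer] = R_FLOOR
        return p.n, p.c, r_eff

    def _row(self, i: int, nn, c_i: float, r_i: float) -> np.ndarray:
        if self.mask.producer[i]:
            return np.full(self.S, P_FLOOR)
        z = (nn - c_i) / (r_i / 2.0)
        return np.clip(self.a * np.exp(-np.minimum(z**2, 700.0)), P_FLOOR, self.a)

    def _col(self, j: int, n_j: float, cc, rr) -> np.ndarray:
        z = (n_j - cc) / (rr / 2.0)
        col = np.clip(self.a * np.exp(-np.minimum(z**2, 700.0)), P_FLOOR, self.a)
        col[self.mask.producer] = P_FLOOR
        return col

    @staticmethod
    def _terms(p, links) -> np.ndarray:
        return np.where(links, np.log(p), np.log1p(-p))

    def _P_full(self, nn, cc, rr) -> np.ndarray:
        z = (nn[None, :] - cc[:, None]) / (rr[:, None] / 2.0)
        P = np.clip(self.a * np.exp(-np.minimum(z**2, 700.0)), P_FLOOR, self.a)
        P[self.mask.producer, :] = P_FLOOR
        return P

    def lnl_of(self, state: np.ndarray) -> float:
        """Full log-likelihood of an arbitrary packed state."""
        nn, cc, rr = self._expand(state)
        return float(self._terms(self._P_full(nn, cc, rr), self.A1).sum())

    def set_state(self, state: np.ndarray) -> float:
        self.state = state.copy()
        self.nn, self.cc, self.rr = self._expand(state)
        self.P = self._P_full(self.nn, self.cc, self.rr)
        self.T = self._terms(self.P, self.A1)
        self.lnl = float(self.T.sum())
        return self.lnl

    # -- single-coordinate proposals --------------------------------------
    def _coupled_row_params(self, s: int, n_s: float, c_s: float):
        """(c, r) of species s after applying the variant's couplings."""
        spec = self.spec
        coeffs = dict(zip(
            spec.global_names, self.state[len(spec.blocks) * self.S :], strict=True
        ))
        if "c" not in spec.blocks:
            c_s = float(np.clip(coeffs["c0"] + coeffs["c1"] * n_s, 0.0, 1.0))
        if "r" in spec.blocks:
            r_s = self.rr[s]
        elif spec.name == "r_of_c":
            r_s = float(np.clip(coeffs["r0"] * math.exp(coeffs["r1"] * c_s),
                                R_FLOOR, R_MAX))
        else:
            r_s = float(np.clip(coeffs["r0"] + coeffs["r1"] * n_s, R_FLOOR, R_MAX))
        if self.mask.producer[s] or self.mask.specialist[s]:
            r_s = R_FLOOR
        return c_s, r_s

    def propose_coord(self, i: int, value: float) -> float:
        kind, s = self.coord_kind[i]
        if kind == "global":
            cand = self.state.copy()
            cand[i] = value
            nn, cc, rr = self._expand(cand)
            P = np.vstack([
                self._row(k, nn, cc[k], rr[k]) for k in range(self.S)
            ])
            T = self._terms(P, self.A1)
            lnl = float(T.sum())
            self._pending = ("full", i, value, nn, cc, rr, P, T, lnl)
            return lnl - self.lnl

        if kind == "n":
            n_s = float(np.clip(value, 0.0, 1.0))
            c_s, r_s = self._coupled_row_params(s, n_s, self.cc[s])
            nn = self.nn.copy()
            nn[s] = n_s
            new_row = self._row(s, nn, c_s, r_s)
            new_col = self._col(s, n_s, self.cc, self.rr)
            new_col[s] = new_row[s]
            rowT = self._terms(new_row, self.A1[s])
            colT = self._terms(new_col, self.A1[:, s])
            delta = (rowT.sum() - self.T[s].sum()) \
                + (colT.sum() - colT[s]) - (self.T[:, s].sum() - self.T[s, s])
            self._pending = ("rowcol", i, value, s, n_s, c_s, r_s,
                             new_row, rowT, new_col, colT, delta)
            return float(delta)

        # c or r coordinate of species s: only row s changes
        if kind == "c":
            c_s = float(np.clip(value, 0.0, 1.0))
            c_s, r_s = self._coupled_row_params(s, self.nn[s], c_s)
        else:
            c_s = self.cc[s]
            r_s = float(np.clip(value, R_FLOOR, R_MAX))
            if self.mask.producer[s] or self.mask.specialist[s]:
                r_s = R_FLOOR
        new_row = self._row(s, self.nn, c_s, r_s)
        rowT = self._terms(new_row, self.A1[s])
        delta = rowT.sum() - self.T[s].sum()
        self._pending = ("row", i, value, s, c_s, r_s, new_row, rowT, delta)
        return float(delta)

    def commit(self) -> None:
        p = self._pending
        if p[0] == "full":
            _, i, value, nn, cc, rr, P, T, lnl = p
            self.state[i] = value
            self.nn, self.cc, self.rr = nn, cc, rr
            self.P, self.T, self.lnl = P, T, lnl
        elif p[0] == "rowcol":
            _, i, value, s, n_s, c_s, r_s, new_row, rowT, new_col, colT, delta = p
            self.state[i] = value
            self.nn[s] = n_s
            self.cc[s] = c_s
            self.rr[s] = r_s
            self.lnl += delta
            self.P[:, s] = new_col
            self.T[:, s] = colT
            self.P[s] = new_row
            self.T[s] = rowT
        else:
            _, i, value, s, c_s, r_s, new_row, rowT, delta = p
            self.state[i] = value
            self.cc[s] = c_s
            self.rr[s] = r_s
            self.lnl += delta
            self.P[s] = new_row
            self.T[s] = rowT
        self._pending = None


def _canonicalize(params: ParamSet, mask: ConstraintMask) -> ParamSet:
    """Pin producer/specialist parameters to their reported convention."""
    c = params.c.copy()
    r = params.r.copy()
    c[mask.producer] = 0.0
    r[mask.producer] = R_FLOOR
    r[mask.specialist] = R_FLOOR
    return ParamSet(n=params.n, c=c, r=r, a=params.a)


def _reorient(params: ParamSet, mask: ConstraintMask, web: FoodWeb) -> ParamSet:
    """Fix the reflection gauge: n should rise with prey count."""
    R = web.A.sum(axis=1)
    rho = stats.spearmanr(params.n, R).statistic
    if np.isnan(rho) or rho >= 0:
        return params
    flipped = ParamSet(n=1.0 - params.n, c=1.0 - params.c, r=params.r, a=params.a)
    return _canonicalize(flipped, mask)


def fit(
    web: FoodWeb,
    spec: ModelSpec,
    config: AnnealConfig | None = None,
    body_mass: np.ndarray | None = None,
) -> FitResult:
    """Simulated-annealing maximum-likelihood fit of a model variant.

    Deterministic given ``config.seed``.  The reported lnL is re-evaluated
    from the returned parameter set, and ties between restarts go to the
    lowest restart index.
    """
    if isinstance(spec, str):
        spec = ModelSpec(spec)
    if spec.name == "random":
        raise ValueError("the random model has a closed form; use variants.random_model")
    config = config or AnnealConfig()
    mask = ConstraintMask.from_web(web)
    if mask.producer.all():
        raise ValueError("web has no consumers: nothing to fit")

    n_allo = None
    if spec.name == "anm":
        mass = body_mass if body_mass is not None else web.body_mass
        if mass is None:
            raise ValueError("the allometric niche model needs body masses")
        n_allo = allometric_niche(mass)

    S = web.S
    lo, hi, optimizable = _layout(spec, S, mask)
    steps = config.steps_per_stage or 50 * optimizable.shape[0]
    obj = _Objective(spec, web, mask, n_allo)
    # species whose packed entries are all live, i.e. swappable wholesale
    swap_ok = ~mask.producer
    if "r" in spec.blocks:
        swap_ok = swap_ok & ~mask.specialist
    swappable = np.nonzero(swap_ok)[0]
    p_swap = config.p_swap if swappable.shape[0] >= 2 else 0.0

    best_state, best_lnl, best_trace = None, -np.inf, None
    for restart in range(config.restarts):
        rng = np.random.default_rng([config.seed, restart])
        if restart == 0:
            state = _warm_start(web, spec, mask, lo, hi)
        else:
            state = lo + (hi - lo) * rng.random(lo.shape[0])
        cur = obj.set_state(state)
        run_best_state, run_best = obj.state.copy(), cur
        trace = np.empty(config.stages)
        T = config.t0
        for stage in range(config.stages):
            coords = optimizable[rng.integers(optimizable.shape[0], size=steps)]
            noise = rng.normal(0.0, config.step_sigma, size=steps)
            move_u = rng.random(size=steps)
            accept_u = rng.random(size=steps)
            for t in range(steps):
                if move_u[t] < p_swap:
                    a_i, b_i = rng.choice(swappable, size=2, replace=False)
                    cand = obj.state.copy()
                    for b in range(len(spec.blocks)):
                        cand[[b * S + a_i, b * S + b_i]] = cand[
                            [b * S + b_i, b * S + a_i]
                        ]
                    cand_lnl = obj.lnl_of(cand)
                    delta = cand_lnl - cur
                    if delta >= 0 or accept_u[t] < math.exp(delta / T):
                        obj.set_state(cand)
                        cur = cand_lnl
                        if cur > run_best:
                            run_best, run_best_state = cur, obj.state.copy()
                    continue
                i = coords[t]
                if move_u[t] < p_swap + config.p_uniform:
                    x = lo[i] + (hi[i] - lo[i]) * rng.random()
                else:
                    x = obj.state[i] + noise[t] * (hi[i] - lo[i])
                    while x < lo[i] or x > hi[i]:  # reflect at the bounds
                        if x < lo[i]:
                            x = 2 * lo[i] - x
                        if x > hi[i]:
                            x = 2 * hi[i] - x
                delta = obj.propose_coord(i, x)
                if delta >= 0 or accept_u[t] < math.exp(delta / T):
                    obj.commit()
                    cur += delta
                    if cur > run_best:
                        run_best, run_best_state = cur, obj.state.copy()
            trace[stage] = run_best
            T *= config.cooling
        if run_best > best_lnl:  # strict: ties go to the earliest restart
            best_lnl, best_state, best_trace = run_best, run_best_state, trace

    params = expand_params(spec, best_state, S, n_allometric=n_allo)
    params = _canonicalize(params, mask)
    if spec.name == "pnm":
        params = _reorient(params, mask, web)
    lnl = log_likelihood(probability_matrix(params, mask), web)
    k = spec.n_params(S)
    return FitResult(
        params=params,
        lnl=lnl,
        k=k,
        aic=aic(lnl, k),
        trace=best_trace,
        seed_used=config.seed,
        model=spec.name,
        config=config,
    )


def _expand_batch(spec, states, S, n_allo):
    """Vectorized expand_params over a batch of packed states (M, k)."""
    M = states.shape[0]
    blocks = {
        name: states[:, b * S : (b + 1) * S] for b, name in enumerate(spec.blocks)
    }
    off = len(spec.blocks) * S
    coeffs = {g: states[:, off + i : off + i + 1] for i, g in enumerate(spec.global_names)}
    if spec.name == "anm":
        n = np.broadcast_to(n_allo, (M, S))
    else:
        n = blocks["n"]
    if "c" in blocks:
        c = blocks["c"]
    else:
        c = coeffs["c0"] + coeffs["c1"] * n
    if "r" in blocks:
        r = blocks["r"]
    elif spec.name == "r_of_c":
        r = coeffs["r0"] * np.exp(coeffs["r1"] * c)
    else:
        r = coeffs["r0"] + coeffs["r1"] * n
    return (
        np.clip(n, 0.0, 1.0),
        np.clip(c, 0.0, 1.0),
        np.clip(r, R_FLOOR, R_MAX),
    )


def grid_search_oracle(
    web: FoodWeb,
    spec: ModelSpec,
    resolution: float = 0.05,
    max_points: int = 10_000_000,
    body_mass: np.ndarray | None = None,
    r_hi: float = R_MAX,
    a: float = A_DEFAULT,
) -> tuple[float, ParamSet]:
    """Exhaustive likelihood maximum over a parameter lattice.

    Grids every free coordinate at the given resolution (pinned producer
    and specialist coordinates are excluded, which is what keeps tiny
    problems inside the ``max_points`` budget) and returns the best lnL
    and the corresponding ParamSet.  Intended as a test oracle for
    :func:`fit` on webs with very few free coordinates.
    """
    if isinstance(spec, str):
        spec = ModelSpec(spec)
    mask = ConstraintMask.from_web(web)
    n_allo = None
    if spec.name == "anm":
        mass = body_mass if body_mass is not None else web.body_mass
        n_allo = allometric_niche(mass)
    S = web.S
    lo, hi, optimizable = _layout(spec, S, mask)

    axes = []
    for i in optimizable:
        if lo[i] == R_FLOOR:  # range-like coordinate: include the floor point
            ax = np.concatenate(
                ([R_FLOOR], np.arange(resolution, min(hi[i], r_hi) + 1e-12, resolution))
            )
        else:
            ax = np.arange(lo[i], hi[i] + 1e-12, resolution)
        axes.append(ax)
    total = math.prod(len(ax) for ax in axes)
    if total > max_points:
        raise ValueError(
            f"grid of {total} points exceeds the {max_points} budget; "
            "coarsen the resolution or reduce the free coordinates"
        )

    base = np.zeros(lo.shape[0])
    base[:] = lo  # pinned coordinates: value irrelevant (mask overrides)
    mesh = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([m.ravel() for m in mesh], axis=1)

    A = web.A.astype(float)
    prod_rows = mask.producer
    spec_rows = mask.specialist
    best_lnl, best_state = -np.inf, None
    chunk = max(1, 200_000 // (S * S))
    for start in range(0, total, chunk):
        block = grid[start : start + chunk]
        states = np.tile(base, (block.shape[0], 1))
        states[:, optimizable] = block
        n, c, r = _expand_batch(spec, states, S, n_allo)
        r = r.copy()
        r[:, spec_rows] = R_FLOOR
        r[:, prod_rows] = R_FLOOR
        z = (n[:, None, :] - c[:, :, None]) / (r[:, :, None] / 2.0)
        P = a * np.exp(-np.minimum(z**2, 700.0))
        P[:, prod_rows, :] = 0.0
        np.clip(P, 1e-10, a, out=P)
        lnls = (A * np.log(P) + (1 - A) * np.log1p(-P)).sum(axis=(1, 2))
        j = int(np.argmax(lnls))
        if lnls[j] > best_lnl:
            best_lnl = float(lnls[j])
            best_state = states[j].copy()

    params = _canonicalize(
        expand_params(spec, best_state, S, n_allometric=n_allo, a=a), mask
    )
    return best_lnl, params
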