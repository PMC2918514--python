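"""Probabilistic niche model kernel.

The model places every species at a niche position ``n`` on a single
trophic axis scaled to [0, 1].  Each consumer ``i`` has a diet position
``c_i`` (the centre of its feeding range) and a feeding range ``r_i``
(its width).  The probability that consumer ``i`` eats resource ``j`` is
a Gaussian in niche distance,

    P_ij = a · exp(−((n_j − c_i) / (r_i / 2))²),

so the half-width ``r_i / 2`` marks the point where the feeding
probability has fallen to ``a/e``.  The peak probability ``a`` is a
single global constant held just below 1 (0.9999) so that no entry of
the probability matrix is ever exactly 0 or 1 and the Bernoulli
log-likelihood

    lnL(θ | D) = Σ_ij [ A_ij ln P_ij + (1 − A_ij) ln(1 − P_ij) ]

stays finite.  The sum runs over all S² entries of the connection
matrix, diagonal included.

Primary producers (species with no prey in the data) have ``c`` fixed at
0 and ``r`` pinned at a tiny floor, which forces all their link
probabilities down to the probability floor.  Specialists (consumers of
a single prey) keep ``c`` free but have ``r`` pinned at the floor, so
their single link is reproduced whenever ``c`` sits on the prey's ``n``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .web_data import FoodWeb

__all__ = [
    "A_DEFAULT",
    "P_FLOOR",
    "R_FLOOR",
    "R_MAX",
    "ParamSet",
    "ConstraintMask",
    "link_probability",
    "probability_matrix",
    "log_likelihood",
    "aic",
    "count_parameters",
    "NOMINAL_PARAMETER_COUNTS",
    "write_params",
    "read_params",
]

#: Global peak link probability (a value of exactly 1 would put ln(1−P)
#: at −inf for observed links predicted perfectly).
A_DEFAULT = 0.9999

#: Floor applied to every link probability so lnL stays finite; the
#: likelihood contribution of a floored non-link is O(1e−10).
P_FLOOR = 1e-10

#: Smallest admissible feeding range; implements the r→0 limit used for
#: producers and specialists without dividing by zero.
R_FLOOR = 1e-6

#: Upper bound on the feeding range.  On a unit niche axis any range
#: above 2 covers the whole axis at near-peak probability, so wider
#: ranges are indistinguishable; the bound fixes the scale gauge.
R_MAX = 2.0


@dataclass
class ParamSet:
    """Per-species niche parameters plus the global peak probability.

    ``n`` (niche position) and ``c`` (diet position) live in [0, 1];
    ``r`` (feeding range) in [R_FLOOR, inf); ``a`` in (0, 1).
    """

    n: np.ndarray
    c: np.ndarray
    r: np.ndarray
    a: float = A_DEFAULT

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        S = self.n.shape[0]
        if self.c.shape != (S,) or self.r.shape != (S,):
            raise ValueError("n, c, r must have equal length")
        if ((self.n < 0) | (self.n > 1)).any():
            raise ValueError("n must lie in [0, 1]")
        if ((self.c < 0) | (self.c > 1)).any():
            raise ValueError("c must lie in [0, 1]")
        if (self.r < R_FLOOR).any():
            raise ValueError(f"r must be >= {R_FLOOR}")
        if not 0.0 < self.a < 1.0:
            raise ValueError("a must lie strictly between 0 and 1")

    @property
    def S(self) -> int:
        return self.n.shape[0]


@dataclass
class ConstraintMask:
    """Which species have pinned parameters, derived from the data.

    ``producer`` flags rows with zero prey (c fixed at 0, r at R_FLOOR);
    ``specialist`` flags rows with exactly one prey (r at R_FLOOR, c
    free).  ``specialist_prey[i]`` is the index of specialist i's sole
    prey, −1 elsewhere.
    """

    producer: np.ndarray
    specialist: np.ndarray
    specialist_prey: np.ndarray

    @classmethod
    def from_web(cls, web: FoodWeb) -> "ConstraintMask":
        R = web.A.sum(axis=1)
        producer = R == 0
        specialist = R == 1
        prey = np.full(web.S, -1, dtype=int)
        for i in np.nonzero(specialist)[0]:
            prey[i] = int(np.nonzero(web.A[i])[0][0])
        return cls(producer=producer, specialist=specialist, specialist_prey=prey)


def link_probability(n_j, c_i, r_i, a: float = A_DEFAULT):
    """Gaussian feeding probability, clamped into [P_FLOOR, a].

    Accepts scalars or broadcastable arrays.  Strictly decreasing in
    |n_j − c_i| (until the floor); equals ``a`` exactly at n_j == c_i and
    ``a/e`` at |n_j − c_i| == r_i / 2.
    """
    r_i = np.asarray(r_i, dtype=float)
    if (r_i <= 0).any() if r_i.ndim else r_i <= 0:
        raise ValueError("feeding range r must be positive")
    if not 0.0 < a < 1.0:
        raise ValueError("a must lie strictly between 0 and 1")
    z = (np.asarray(n_j, dtype=float) - np.asarray(c_i, dtype=float)) / (r_i / 2.0)
    p = a * np.exp(-(z**2))
    return np.clip(p, P_FLOOR, a)


def probability_matrix(
    params: ParamSet, mask: ConstraintMask | None = None
) -> np.ndarray:
    """S×S matrix of link probabilities, rows = consumers.

    With a constraint mask, producer rows are floored wholesale and
    specialist rows use r = R_FLOOR regardless of the stored value.
    """
    S = params.S
    r_eff = params.r.copy()
    if mask is not None:
        if mask.producer.shape != (S,):
            raise ValueError("constraint mask length does not match ParamSet")
        r_eff[mask.specialist] = R_FLOOR
        r_eff[mask.producer] = R_FLOOR
    z = (params.n[None, :] - params.c[:, None]) / (r_eff[:, None] / 2.0)
    P = params.a * np.exp(-np.minimum(z**2, 700.0))
    if mask is not None:
        P[mask.producer, :] = P_FLOOR
    return np.clip(P, P_FLOOR, params.a)


def log_likelihood(P: np.ndarray, web: FoodWeb | np.ndarray) -> float:
    """Bernoulli log-likelihood of the observed matrix under P.

    Sums over all S² entries, diagonal included.  Every entry of P must
    lie strictly inside (0, 1); the floors applied upstream guarantee
    this for matrices built by :func:`probability_matrix`.
    """
    A = web.A if isinstance(web, FoodWeb) else np.asarray(web)
    P = np.asarray(P, dtype=float)
    if P.shape != A.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs A {A.shape}")
    if (P <= 0).any() or (P >= 1).any():
        raise ValueError("all link probabilities must lie strictly in (0, 1)")
    return float(np.where(A == 1, np.log(P), np.log1p(-P)).sum())


def aic(lnl: float, k: int) -> float:
    """Akaike information criterion, 2k − 2·lnL."""
    if k < 0:
        raise ValueError("parameter count k must be non-negative")
    return 2.0 * k - 2.0 * lnl


#: Nominal free-parameter count of each model variant as a function of
#: S.  Counting is nominal: parameters pinned for producers and
#: specialists are not subtracted.
NOMINAL_PARAMETER_COUNTS = {
    "pnm": lambda S: 3 * S,            # n, c, r free per species
    "anm": lambda S: 2 * S,            # n from body mass; c, r free
    "r_of_c": lambda S: 2 * S + 2,     # n, c free; r = r0·exp(r1·c)
    "r_of_n": lambda S: 2 * S + 2,     # n, c free; r = r0 + r1·n
    "c_of_n": lambda S: 2 * S + 2,     # n, r free; c = c0 + c1·n
    "c_and_r_of_n": lambda S: S + 4,   # n free; c, r linear in n
    "random": lambda S: 1,             # single uniform link probability
}


def count_parameters(spec, S: int) -> int:
    """Nominal parameter count k of a model variant at S species."""
    name = getattr(spec, "name", spec)
    try:
        return NOMINAL_PARAMETER_COUNTS[name](S)
    except KeyError:
        raise ValueError(f"unknown model variant {name!r}") from None


def write_params(
    params: ParamSet,
    species: list[str],
    csv_path: str | Path,
    meta: dict | None = None,
) -> None:
    """Write a ParamSet as CSV (species, n, c, r) + JSON sidecar for a."""
    csv_path = Path(csv_path)
    pd.DataFrame(
        {"species": species, "n": params.n, "c": params.c, "r": params.r}
    ).to_csv(csv_path, index=False)
    sidecar = {"a": params.a}
    if meta:
        sidecar.update(meta)
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1) + "\n")


def read_params(csv_path: str | Path) -> tuple[ParamSet, list[str]]:
    """Read a ParamSet CSV written by :func:`write_params`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    a = A_DEFAULT
    sidecar = csv_path.with_suffix(".json")
    if sidecar.exists():
        a = float(json.loads(sidecar.read_text()).get("a", A_DEFAULT))
    params = ParamSet(
        n=df["n"].to_numpy(),
        c=df["c"].to_numpy(),
        r=np.maximum(df["r"].to_numpy(), R_FLOOR),
        a=a,
    )
    return params, [str(s) for s in df["species"]]
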