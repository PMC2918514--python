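"""Model family: full PNM, allometric niche model, reduced couplings, random baseline.

The full probabilistic niche model (PNM) frees n, c and r for every
species (3S parameters).  The reduced variants replace one or two of the
per-species vectors by a two-coefficient function of another parameter:

=============   ================================  ==========
name            coupling                          nominal k
=============   ================================  ==========
pnm             none                              3S
anm             n from log body mass              2S
r_of_c          r = r0·exp(r1·c)                  2S + 2
r_of_n          r = r0 + r1·n                     2S + 2
c_of_n          c = c0 + c1·n                     2S + 2
c_and_r_of_n    c = c0 + c1·n, r = r0 + r1·n      S + 4
random          single uniform link probability   1
=============   ================================  ==========

The random baseline has the closed-form maximum at p = L/S² and needs
no optimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .pnm_core import (
    A_DEFAULT,
    R_FLOOR,
    R_MAX,
    ParamSet,
    aic,
    count_parameters,
)

__all__ = [
    "VARIANT_NAMES",
    "ModelSpec",
    "RandomModelResult",
    "allometric_niche",
    "expand_params",
    "random_model",
    "MPNM_REFERENCE",
]

VARIANT_NAMES = (
    "pnm",
    "anm",
    "r_of_c",
    "r_of_n",
    "c_of_n",
    "c_and_r_of_n",
    "random",
)

# Per-species parameter blocks packed for each variant, in order, followed
# by the global coefficient names.
_BLOCKS = {
    "pnm": (("n", "c", "r"), ()),
    "anm": (("c", "r"), ()),
    "r_of_c": (("n", "c"), ("r0", "r1")),
    "r_of_n": (("n", "c"), ("r0", "r1")),
    "c_of_n": (("n", "r"), ("c0", "c1")),
    "c_and_r_of_n": (("n",), ("c0", "c1", "r0", "r1")),
}

#: Published reference constants for the minimum potential niche model on
#: the Benguela web, reported in comparison tables but not implemented.
MPNM_REFERENCE = {"k": 32, "lnl": -214.0, "aic": 493.0}


@dataclass
class ModelSpec:
    """Names a model variant and carries its packed-vector layout.

    ``coefficients`` holds fitted global coefficients (c0, c1, r0, r1)
    once known; it is informational — :func:`expand_params` reads the
    coefficients from the packed vector itself.
    """

    name: str
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in VARIANT_NAMES:
            raise ValueError(
                f"unknown model variant {self.name!r}; expected one of {VARIANT_NAMES}"
            )
        if self.name in _BLOCKS:
            allowed = set(_BLOCKS[self.name][1])
            extra = set(self.coefficients) - allowed
            if extra:
                raise ValueError(
                    f"variant {self.name!r} takes no coefficients {sorted(extra)}"
                )

    @property
    def blocks(self) -> tuple[str, ...]:
        """Per-species parameter blocks packed for this variant."""
        return _BLOCKS[self.name][0]

    @property
    def global_names(self) -> tuple[str, ...]:
        """Global coefficient names appended after the species blocks."""
        return _BLOCKS[self.name][1]

    def n_params(self, S: int) -> int:
        return count_parameters(self.name, S)


def allometric_niche(body_mass: np.ndarray) -> np.ndarray:
    """Niche positions from log body mass, normalized onto [0, 1].

    n_i = (log10 m_i − log10 m_min) / (log10 m_max − log10 m_min), so the
    lightest species sits at 0 and the heaviest at 1.  Order-preserving
    and invariant to rescaling all masses by a constant.
    """
    m = np.asarray(body_mass, dtype=float)
    if not (np.isfinite(m) & (m > 0)).all():
        raise ValueError("body masses must be positive and finite")
    logm = np.log10(m)
    span = logm.max() - logm.min()
    if span <= 0:
        raise ValueError("all body masses equal: niche axis is degenerate")
    return (logm - logm.min()) / span


def expand_params(
    spec: ModelSpec,
    packed: np.ndarray,
    S: int,
    n_allometric: np.ndarray | None = None,
    a: float = A_DEFAULT,
) -> ParamSet:
    """Unpack a packed free-parameter vector into a full ParamSet.

    The packed vector has the nominal length ``count_parameters(spec, S)``:
    the per-species blocks of the variant in order, then its global
    coefficients.  Coupled parameters are computed from their source
    parameter and clamped into the model bounds (c into [0, 1], r into
    [R_FLOOR, R_MAX]).  The full PNM passes values through unchanged.
    """
    if spec.name == "random":
        raise ValueError("the random model has no per-species parameters")
    packed = np.asarray(packed, dtype=float)
    expect = spec.n_params(S)
    if packed.shape != (expect,):
        raise ValueError(
            f"packed vector length {packed.shape} != nominal count {expect} "
            f"for variant {spec.name!r} at S={S}"
        )
    blocks = {
        name: packed[i * S : (i + 1) * S] for i, name in enumerate(spec.blocks)
    }
    coeffs = dict(
        zip(spec.global_names, packed[len(spec.blocks) * S :], strict=True)
    )

    if spec.name == "anm":
        if n_allometric is None:
            raise ValueError("the allometric niche model needs body-mass niche positions")
        n = np.asarray(n_allometric, dtype=float)
        if n.shape != (S,):
            raise ValueError("allometric n length does not match S")
    else:
        n = blocks["n"]

    if "c" in blocks:
        c = blocks["c"]
    else:  # c = c0 + c1·n
        c = coeffs["c0"] + coeffs["c1"] * n

    if "r" in blocks:
        r = blocks["r"]
    elif spec.name == "r_of_c":
        r = coeffs["r0"] * np.exp(coeffs["r1"] * c)
    else:  # linear r = r0 + r1·n
        r = coeffs["r0"] + coeffs["r1"] * n

    return ParamSet(
        n=np.clip(n, 0.0, 1.0),
        c=np.clip(c, 0.0, 1.0),
        r=np.clip(r, R_FLOOR, R_MAX),
        a=a,
    )


@dataclass
class RandomModelResult:
    """Closed-form maximum likelihood of the uniform-probability model."""

    p: float
    lnl: float
    aic: float
    k: int = 1


def random_model(S: int, L: int) -> RandomModelResult:
    """Random (uniform-p) baseline with its closed-form maximum.

    The Bernoulli likelihood over S² exchangeable entries is maximized at
    p = L/S², giving lnL = S²·[C·ln C + (1−C)·ln(1−C)] with C = L/S², and
    AIC = 2·1 − 2·lnL.
    """
    if not 0 < L < S * S:
        raise ValueError(
            f"random model needs 0 < L < S² (got L={L}, S²={S * S}): "
            "an empty or complete web has a degenerate likelihood"
        )
    C = L / S**2
    lnl = S**2 * (C * math.log(C) + (1 - C) * math.log(1 - C))
    return RandomModelResult(p=C, lnl=lnl, aic=aic(lnl, 1))
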