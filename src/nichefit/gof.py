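"""Goodness-of-fit statistics for a probability matrix against an observed web.

The headline statistic is the expected fraction of observed links the
model predicts correctly when realized at the fitted parameters,
f_L = N1 / L with N1 = Σ_{A_ij = 1} P_ij, together with the expected
fraction of all S² connection-matrix entries (links and non-links)
predicted correctly.  Both are decomposed per species: n_Ri / f_Ri on
the prey (row) side and n_Ci / f_Ci on the predator (column) side, with
fractions undefined (NaN) for species without prey or predators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .web_data import FoodWeb

__all__ = ["GofReport", "gof_report", "flag_poorly_predicted"]


@dataclass
class GofReport:
    species: list[str]
    expected_links: float      # Σ_ij P_ij
    N1: float                  # Σ over observed links of P_ij
    f_L: float                 # N1 / L
    entries_correct: float     # Σ_ij [A·P + (1−A)(1−P)] / S²
    n_R: np.ndarray            # per consumer, expected prey links correct
    f_R: np.ndarray            # n_R / R_i (NaN when R_i = 0)
    n_C: np.ndarray            # per resource, expected predator links correct
    f_C: np.ndarray            # n_C / C_i (NaN when C_i = 0)
    R: np.ndarray
    Cn: np.ndarray

    def per_species_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "R": self.R,
                "C": self.Cn,
                "n_R": self.n_R,
                "f_R": self.f_R,
                "n_C": self.n_C,
                "f_C": self.f_C,
            }
        )

    def summary(self) -> dict:
        return {
            "expected_links": self.expected_links,
            "N1": self.N1,
            "f_L": self.f_L,
            "entries_correct": self.entries_correct,
        }


def gof_report(P: np.ndarray, web: FoodWeb) -> GofReport:
    """Expected-prediction report of P against the observed matrix.

    All sums run over the full S² matrix, diagonal included.  Every
    entry of P must lie strictly in (0, 1).
    """
    P = np.asarray(P, dtype=float)
    A = web.A
    if P.shape != A.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs A {A.shape}")
    if (P <= 0).any() or (P >= 1).any():
        raise ValueError("probabilities must lie strictly in (0, 1)")
    links = A == 1
    R = A.sum(axis=1)
    Cn = A.sum(axis=0)
    L = int(A.sum())
    if L == 0:
        raise ValueError("web has no links: f_L is undefined")
    PA = np.where(links, P, 0.0)
    n_R = PA.sum(axis=1)
    n_C = PA.sum(axis=0)
    N1 = float(PA.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        f_R = np.where(R > 0, n_R / np.maximum(R, 1), np.nan)
        f_C = np.where(Cn > 0, n_C / np.maximum(Cn, 1), np.nan)
    return GofReport(
        species=list(web.species),
        expected_links=float(P.sum()),
        N1=N1,
        f_L=N1 / L,
        entries_correct=float(np.where(links, P, 1.0 - P).mean()),
        n_R=n_R,
        f_R=f_R,
        n_C=n_C,
        f_C=f_C,
        R=R,
        Cn=Cn,
    )


def flag_poorly_predicted(
    report: GofReport, threshold: float = 0.65
) -> dict[str, list[str]]:
    """Species whose prey (f_R) or predator (f_C) links are poorly predicted.

    Returns ``{"prey": [...], "predators": [...]}``: consumers whose
    expected fraction of prey links correct is ≤ threshold, and resources
    whose expected fraction of predator links correct is ≤ threshold.
    Undefined fractions (basal species / top predators) are never flagged.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    prey_side = [
        s for s, f in zip(report.species, report.f_R) if np.isfinite(f) and f <= threshold
    ]
    predator_side = [
        s for s, f in zip(report.species, report.f_C) if np.isfinite(f) and f <= threshold
    ]
    return {"prey": prey_side, "predators": predator_side}
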