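"""KDIGO health-state grid for chronic kidney disease.

The grid crosses six eGFR categories (G1, G2, G3a, G3b, G4, G5) with three
albuminuria categories (A1-A3), giving 18 alive, non-KRT states.  Kidney
replacement therapy (KRT) adds HEMODIALYSIS, PERITONEAL_DIALYSIS and
TRANSPLANT; DEAD is absorbing.

Boundary conventions (fixed, bit-exact):

* eGFR (mL/min/1.73 m^2): G1 >= 90, G2 [60, 90), G3a [45, 60),
  G3b [30, 45), G4 [15, 30), G5 < 15 -- half-open with G1 closed above.
* UACR (mg/g): A1 < 30, A2 [30, 300] (closed on both printed bounds),
  A3 > 300.
"""

from __future__ import annotations

import enum

import numpy as np

from .errors import DomainError

#: ascending eGFR category edges; np.digitize maps eGFR to 0..5 below
EGFR_EDGES = np.array([15.0, 30.0, 45.0, 60.0, 90.0])

UACR_A1_UPPER = 30.0   # A1 strictly below
UACR_A3_LOWER = 300.0  # A3 strictly above

G_LABELS = ("G1", "G2", "G3a", "G3b", "G4", "G5")
A_LABELS = ("A1", "A2", "A3")

#: eGFR bounds per G label, [lower, upper) except G1 unbounded above
G_BOUNDS = {
    "G1": (90.0, np.inf),
    "G2": (60.0, 90.0),
    "G3a": (45.0, 60.0),
    "G3b": (30.0, 45.0),
    "G4": (15.0, 30.0),
    "G5": (0.0, 15.0),
}


class HealthState(enum.IntEnum):
    """One of the 18 KDIGO grid states, a KRT modality, or DEAD.

    Grid states are encoded as ``3 * g_index + a_index`` with g_index 0..5
    running G1..G5 and a_index 0..2 running A1..A3, so vectorised code can
    operate on the integer codes directly.
    """

    G1A1 = 0
    G1A2 = 1
    G1A3 = 2
    G2A1 = 3
    G2A2 = 4
    G2A3 = 5
    G3aA1 = 6
    G3aA2 = 7
    G3aA3 = 8
    G3bA1 = 9
    G3bA2 = 10
    G3bA3 = 11
    G4A1 = 12
    G4A2 = 13
    G4A3 = 14
    G5A1 = 15
    G5A2 = 16
    G5A3 = 17
    HEMODIALYSIS = 18
    PERITONEAL_DIALYSIS = 19
    TRANSPLANT = 20
    DEAD = 21

    @property
    def is_grid(self) -> bool:
        return self < 18

    @property
    def is_krt(self) -> bool:
        return 18 <= self <= 20

    @property
    def g_label(self) -> str:
        if not self.is_grid:
            raise DomainError(f"{self.name} is not a KDIGO grid state")
        return G_LABELS[self // 3]

    @property
    def a_label(self) -> str:
        if not self.is_grid:
            raise DomainError(f"{self.name} is not a KDIGO grid state")
        return A_LABELS[self % 3]


GRID_STATES = tuple(HealthState(i) for i in range(18))
KRT_STATES = (
    HealthState.HEMODIALYSIS,
    HealthState.PERITONEAL_DIALYSIS,
    HealthState.TRANSPLANT,
)

N_GRID_STATES = 18


def g_index(egfr: np.ndarray | float) -> np.ndarray:
    """Vectorised eGFR category index: 0=G1 ... 5=G5."""
    return 5 - np.digitize(np.asarray(egfr, dtype=float), EGFR_EDGES)


def a_index(uacr: np.ndarray | float) -> np.ndarray:
    """Vectorised albuminuria category index: 0=A1, 1=A2, 2=A3."""
    u = np.asarray(uacr, dtype=float)
    return np.where(u < UACR_A1_UPPER, 0, np.where(u <= UACR_A3_LOWER, 1, 2))


def classify_codes(egfr: np.ndarray, uacr: np.ndarray) -> np.ndarray:
    """Map arrays of positive eGFR/UACR values to grid state codes 0..17.

    Raises :class:`DomainError` if any value is non-positive or non-finite.
    """
    e = np.asarray(egfr, dtype=float)
    u = np.asarray(uacr, dtype=float)
    if e.size and (not np.all(np.isfinite(e)) or np.any(e <= 0)):
        raise DomainError("eGFR must be positive and finite")
    if u.size and (not np.all(np.isfinite(u)) or np.any(u <= 0)):
        raise DomainError("UACR must be positive and finite")
    return (3 * g_index(e) + a_index(u)).astype(np.int64)


def classify_state(egfr: float, uacr: float) -> HealthState:
    """Classify a single (eGFR, UACR) pair into its unique grid state.

    >>> classify_state(56, 75).name
    'G3aA2'
    """
    code = classify_codes(np.array([egfr]), np.array([uacr]))[0]
    return HealthState(int(code))


def state_egfr_bounds(g_label: str) -> tuple[float, float]:
    """eGFR [lower, upper) bounds of a G category label."""
    try:
        return G_BOUNDS[g_label]
    except KeyError as exc:  # pragma: no cover - defensive
        raise DomainError(f"unknown G category {g_label!r}") from exc
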