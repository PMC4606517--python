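"""Published reference values for the Ago2 t1-nucleotide study system.

These are the measured parameters of human Argonaute2 loaded with a guide
RNA binding short seed-matched target RNAs that differ only in the target
nucleotide opposite guide position 1 (the "t1" nucleotide).  They serve two
roles: defaults for the synthetic-data generators (so simulations reproduce
the study conditions), and inputs to the derived-quantity arithmetic
(fold-affinity ratios, average dwell times) that the reporting layer
recomputes.

Units: Kd in nM; dwell time constants in seconds; kon_obs in s^-1 nM^-1;
population fractions dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "KD_WT_NM",
    "KD_A481T_NM",
    "NON_A_T1_NUCLEOTIDES",
    "DwellKinetics",
    "DWELL_KINETICS",
    "KON_OBS",
    "FRAME_INTERVAL_S",
    "RECEPTOR_TOTAL_NM",
    "TITRATION_MAX_NM",
]

# Equilibrium dissociation constants (nM) for wild-type Ago2-guide against
# t1-variant targets, dot-blot titrations 0-70 nM protein, 0.1 nM target.
KD_WT_NM: dict[str, float] = {
    "A": 0.75,
    "G": 1.9,
    "U": 1.9,
    "C": 1.8,
    "DAP": 0.45,   # 2,6-diaminopurine
    "I": 1.7,      # inosine
    "m6A": 1.8,    # N6-methyladenosine
}

# Reported fit uncertainties on the wild-type Kds (nM).
KD_WT_SE_NM: dict[str, float] = {
    "A": 0.04, "G": 0.09, "U": 0.10, "C": 0.12,
    "DAP": 0.03, "I": 0.09, "m6A": 0.12,
}

# The A481T pocket mutant loses t1A preference: t1A and t1G bind alike.
KD_A481T_NM: dict[str, float] = {"A": 1.5, "G": 1.8}

NON_A_T1_NUCLEOTIDES: tuple[str, ...] = ("G", "U", "C", "I", "m6A")


@dataclass(frozen=True)
class DwellKinetics:
    """Dwell-time parameters for one t1 condition from smFRET.

    A single-exponential condition has ``tau_long`` and ``p_long`` unset.
    ``p_short``/``p_long`` are event-count fractions (they sum to 1).
    """

    tau_short: float                  # s
    tau_long: Optional[float] = None  # s
    p_short: float = 1.0
    r_squared: float = float("nan")

    @property
    def p_long(self) -> float:
        return 1.0 - self.p_short

    @property
    def average_dwell(self) -> float:
        if self.tau_long is None:
            return self.tau_short
        return self.p_short * self.tau_short + self.p_long * self.tau_long


# smFRET dwell-time fits per t1 nucleotide (0.1 s frames).  t1U is single
# exponential; t1A and t1DAP resolve two populations of roughly equal size,
# the short one matching t1U and the long one >5x slower to dissociate.
DWELL_KINETICS: dict[str, DwellKinetics] = {
    "U": DwellKinetics(tau_short=1.64, r_squared=0.994),
    "A": DwellKinetics(tau_short=1.61, tau_long=8.69, p_short=0.498,
                       r_squared=0.998),
    "DAP": DwellKinetics(tau_short=1.97, tau_long=12.87, p_short=0.446,
                         r_squared=0.996),
}

# Apparent association rates (s^-1 nM^-1) from accumulated first arrivals;
# near-identical across t1 nucleotides.
KON_OBS: dict[str, float] = {"U": 0.040, "A": 0.033, "DAP": 0.041}

FRAME_INTERVAL_S: float = 0.1
RECEPTOR_TOTAL_NM: float = 0.1
TITRATION_MAX_NM: float = 70.0
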