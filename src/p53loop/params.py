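"""Model parameters for the p53-Mdm2 negative feedback loop.

The loop couples nuclear p53 (p), mdm2 mRNA (m_m), free Mdm2 protein (m)
and the p53-Mdm2 complex (c).  p53 transactivates mdm2 with a Hill
coefficient of 2 (double binding site at the mdm2 promoter); Mdm2 binds
p53 and targets it for degradation, closing the negative loop.

Units are nM and hours throughout the deterministic layer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["ModelParameters", "default_parameters", "PARAMETER_NAMES"]

#: Names accepted by fold-change machinery.  ``k_D`` is derived
#: (k_D = k_b / k_f) and is applied by rewriting k_f with k_b held fixed.
PARAMETER_NAMES = (
    "sigma",
    "alpha",
    "delta",
    "k_t",
    "k_tl",
    "beta",
    "gamma",
    "k_b",
    "k_f",
    "k_D",
)


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants of the p53-Mdm2 feedback loop.

    Attributes
    ----------
    sigma : float
        p53 production rate, nM/h.  May be zero (production switched off);
        every other rate must be strictly positive.
    alpha : float
        Mdm2-independent p53 removal rate (degradation, nuclear export,
        sequestration...), 1/h.
    delta : float
        Mdm2-dependent p53 degradation rate, acting on the complex, 1/h.
    k_t : float
        mdm2 transcription rate constant (Hill-2 activation by p53),
        1/(nM*h).
    k_tl : float
        Mdm2 translation rate per mRNA, 1/h.
    beta : float
        mdm2 mRNA degradation rate, 1/h.
    gamma : float
        Mdm2 removal rate, identical for free and complexed Mdm2, 1/h.
    k_b : float
        p53-Mdm2 complex dissociation rate, 1/h.
    k_f : float
        p53-Mdm2 complex formation rate, 1/(nM*h).
    hill : float
        Hill exponent of mdm2 activation by p53; fixed at 2 unless
        explicitly overridden.
    """

    sigma: float = 1000.0
    alpha: float = 0.1
    delta: float = 11.0
    k_t: float = 0.03
    k_tl: float = 1.4
    beta: float = 0.6
    gamma: float = 0.2
    k_b: float = 7200.0
    k_f: float = 5000.0
    hill: float = 2.0

    def __post_init__(self) -> None:
        if not (self.sigma >= 0.0):
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        for name in ("alpha", "delta", "k_t", "k_tl", "beta", "gamma", "k_b", "k_f"):
            value = getattr(self, name)
            if not (value > 0.0):
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if not (self.hill > 0.0):
            raise ValueError(f"hill must be strictly positive, got {self.hill}")

    @property
    def k_D(self) -> float:
        """Dissociation constant k_D = k_b / k_f, nM."""
        return self.k_b / self.k_f

    def with_updates(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced.

        ``k_D`` is accepted as a pseudo-field: setting it rewrites
        ``k_f = k_b / k_D`` with ``k_b`` held fixed.
        """
        if "k_D" in changes:
            k_D = changes.pop("k_D")
            if "k_f" in changes:
                raise ValueError("cannot set both k_f and k_D")
            if not (k_D > 0):
                raise ValueError(f"k_D must be strictly positive, got {k_D}")
            k_b = changes.get("k_b", self.k_b)
            changes["k_f"] = k_b / k_D
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def default_parameters() -> ModelParameters:
    """Default rate constants of the loop.

    sigma=1000 nM/h, alpha=0.1/h, delta=11/h, k_t=0.03/(nM h),
    k_tl=1.4/h, beta=0.6/h, gamma=0.2/h, k_b=7200/h and k_D=1.44 nM,
    hence k_f = k_b/k_D = 5000/(nM h).
    """
    return ModelParameters()
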