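"""Distribution-of-fitness-effects models and frequency-dependent selection.

Two DFE families are supported: *constant* (every beneficial mutation adds
``mean_ben`` to fitness and every deleterious one subtracts ``|mean_del|``) and
*exponential* (effects drawn from exponential distributions with those means).
Also provides the linear frequency-dependent selection coefficient
``s(x) = b + m*x`` used by the two-allele control model, whose interior root at
``x = -b/m`` is a genuine frequency threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DfeSpec", "FreqDepParams", "draw_effect", "freq_dep_s"]


@dataclass(frozen=True)
class DfeSpec:
    """DFE family and its means.

    ``mean_del`` is stored as conventionally printed (non-positive); draws use
    its magnitude and are negated.
    """

    mode: str = "constant"
    mean_ben: float = 0.1
    mean_del: float = -0.1

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "exponential"):
            raise ValueError(f"mode must be 'constant' or 'exponential', got {self.mode!r}")
        if self.mean_ben <= 0:
            raise ValueError(f"mean_ben must be > 0, got {self.mean_ben}")
        if self.mean_del > 0:
            raise ValueError(f"mean_del must be <= 0, got {self.mean_del}")


@dataclass(frozen=True)
class FreqDepParams:
    """Linear frequency-dependent selection s(x) = b + m_slope * x.

    ``m_slope`` is named to avoid collision with the mutator fold ``m_fold``.
    With b < 0 < b + m_slope the coefficient changes sign at x = -b/m_slope.
    """

    b: float
    m_slope: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.b) and np.isfinite(self.m_slope)):
            raise ValueError("b and m_slope must be finite")


def draw_effect(kind: str, spec: DfeSpec, rng: np.random.Generator) -> float:
    """Draw one fitness effect of the given kind ('beneficial'|'deleterious').

    Constant mode returns the configured mean exactly; exponential mode returns
    +Exp(mean_ben) for beneficial and -Exp(|mean_del|) for deleterious draws.
    """
    if kind not in ("beneficial", "deleterious"):
        raise ValueError(f"kind must be 'beneficial' or 'deleterious', got {kind!r}")
    if spec.mode == "constant":
        return spec.mean_ben if kind == "beneficial" else spec.mean_del
    if kind == "beneficial":
        return float(rng.exponential(spec.mean_ben))
    return -float(rng.exponential(abs(spec.mean_del)))


def freq_dep_s(x, p: FreqDepParams):
    """Selection coefficient s(x) = b + m_slope * x for frequency x in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("frequency x must be in [0, 1]")
    s = p.b + p.m_slope * x
    return float(s) if s.ndim == 0 else s
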