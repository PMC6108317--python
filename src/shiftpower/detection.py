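"""Shared detection-outcome record for the BiSSE and stepwise-AIC detectors."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class DetectionResult:
    """Outcome of one shift-detection attempt on one tree.

    For the likelihood-ratio (BiSSE) detectors ``detected`` is equivalent
    to ``p_value < 0.05``; for the stepwise-AIC detector the statistic,
    degrees of freedom and p-value are not defined and stay ``None``.
    """

    method: str
    detected: bool
    stat: float | None = None  # 2 * delta lnL
    df: int | None = None
    p_value: float | None = None
    model_unequal: str | None = None
    model_equal: str | None = None
    extra: dict = field(default_factory=dict)
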