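"""Three-segment clamp protocols: pre-clamp, clamp, post-clamp.

A protocol applies a baseline value before and after a clamp segment during
which the amplitude is applied — injected current (nA) under current clamp,
holding voltage (mV) under voltage clamp.  Defaults are a 70 ms run
(10 / 50 / 10 ms); total simulated time is capped at 1,000 ms.

Segment boundaries are half-open and left-inclusive, so the instant t = pre_ms
belongs to the clamp segment and t = pre_ms + clamp_ms to the post-clamp
segment; with dt dividing the durations this makes step counts exact.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ClampProtocol", "ProtocolError", "default_protocol", "validate",
           "stimulus_at", "TOTAL_CAP_MS"]

#: Maximum total simulated time, ms.
TOTAL_CAP_MS = 1000.0

_MODES = ("current", "voltage")


class ProtocolError(ValueError):
    """Invalid clamp protocol."""


@dataclass(frozen=True)
class ClampProtocol:
    """Mode plus segment durations and amplitudes.

    ``amplitude`` is in nA (current mode) or mV (voltage mode).  ``baseline``
    is applied outside the clamp segment; ``None`` in voltage mode means
    "hold at the model's numerically located resting potential" (resolved by
    the simulator), and defaults to 0 nA in current mode.
    """

    mode: str
    amplitude: float = 0.0
    pre_ms: float = 10.0
    clamp_ms: float = 50.0
    post_ms: float = 10.0
    baseline: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ProtocolError(
                f"unknown mode {self.mode!r}; expected one of {_MODES}")

    @property
    def total_ms(self) -> float:
        return self.pre_ms + self.clamp_ms + self.post_ms

    def resolved_baseline(self) -> float:
        """Baseline with the current-mode default of 0 nA applied."""
        if self.baseline is None and self.mode == "current":
            return 0.0
        if self.baseline is None:
            raise ProtocolError("voltage-mode baseline unresolved; the "
                                "simulator substitutes the resting potential")
        return self.baseline


def default_protocol(mode: str, amplitude: float = 0.0) -> ClampProtocol:
    """The default 70 ms protocol: 10 ms pre-clamp, 50 ms clamp, 10 ms post."""
    return validate(ClampProtocol(mode=mode, amplitude=amplitude))


def validate(protocol: ClampProtocol) -> ClampProtocol:
    """Check durations; returns the protocol unchanged (idempotent).

    Durations must be non-negative, the total positive and at most the
    1,000 ms cap.
    """
    for name in ("pre_ms", "clamp_ms", "post_ms"):
        if getattr(protocol, name) < 0:
            raise ProtocolError(f"{name} must be non-negative, "
                                f"got {getattr(protocol, name)}")
    if protocol.total_ms <= 0:
        raise ProtocolError("total duration must be positive")
    if protocol.total_ms > TOTAL_CAP_MS:
        raise ProtocolError(
            f"total duration {protocol.total_ms:g} ms exceeds the "
            f"{TOTAL_CAP_MS:g} ms cap")
    return protocol


def stimulus_at(protocol: ClampProtocol, t: float,
                baseline: float | None = None) -> float:
    """Applied value (nA or mV) at time t.

    Baseline on [0, pre) and [pre+clamp, total]; amplitude on
    [pre, pre+clamp).  ``baseline`` overrides the protocol's own (used when
    the simulator has resolved a voltage-mode resting baseline).
    """
    if t < 0 or t > protocol.total_ms:
        raise ProtocolError(
            f"t={t} ms outside protocol span [0, {protocol.total_ms}] ms")
    base = protocol.resolved_baseline() if baseline is None else baseline
    if protocol.pre_ms <= t < protocol.pre_ms + protocol.clamp_ms:
        return protocol.amplitude
    return base
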