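"""Task protocol: block timing for the movement-evoked pain and VR conditions.

The session layout mirrors the acquisition protocol: a movement-evoked pain
paradigm on the noninjured limb first (hold-move-hold cycles repeated
``n_cycles`` times, each cycle contributing two 5 s holds), then the injured
limb, a rest period, and two 6-minute VR blocks (guided relaxation, then a
focused-attention distraction game). Block membership uses half-open
intervals ``[onset, onset + duration)`` in seconds from recording start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

#: Canonical condition labels, in session order.
CONDITION_NONINJURED = "noninjured"
CONDITION_INJURED = "injured"
CONDITION_RELAXATION = "relaxation"
CONDITION_DISTRACTION = "distraction"
CONDITIONS = (
    CONDITION_NONINJURED,
    CONDITION_INJURED,
    CONDITION_RELAXATION,
    CONDITION_DISTRACTION,
)


@dataclass(frozen=True)
class Block:
    label: str
    onset: float      # seconds from recording start
    duration: float   # seconds

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class CycleParams:
    """Timing of one hold-move-hold cycle of the movement paradigm."""

    move_s: float = 2.5   # slow uniform movement to end range / +5 degrees
    hold_s: float = 5.0   # static hold at first pain threshold
    relax_s: float = 3.0  # return to rest between cycles
    n_cycles: int = 10    # cycles per side; each cycle has two holds

    def __post_init__(self) -> None:
        if self.move_s <= 0 or self.hold_s <= 0 or self.relax_s <= 0:
            raise InvalidParameterError("cycle durations must be positive")
        if self.n_cycles <= 0:
            raise InvalidParameterError("n_cycles must be a positive integer")

    @property
    def cycle_s(self) -> float:
        # move, hold, move ~5 degrees further, hold, relax
        return 2 * self.move_s + 2 * self.hold_s + self.relax_s

    @property
    def side_s(self) -> float:
        return self.n_cycles * self.cycle_s


@dataclass
class TaskDesign:
    """Ordered, non-overlapping labeled blocks over one recording."""

    blocks: list[Block]
    sampling_rate: float
    total_duration: float

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive")
        last_end = -np.inf
        for b in self.blocks:
            if b.onset < last_end:
                raise InvalidParameterError(
                    f"blocks overlap or are unordered at onset {b.onset}"
                )
            if b.end > self.total_duration + 1e-9:
                raise InvalidParameterError(
                    f"block {b.label!r} ends at {b.end} s, beyond the "
                    f"{self.total_duration} s record"
                )
            last_end = b.end

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sampling_rate))

    @property
    def condition_labels(self) -> list[str]:
        seen: list[str] = []
        for b in self.blocks:
            if b.label not in seen:
                seen.append(b.label)
        return seen

    def blocks_for(self, label: str) -> list[Block]:
        return [b for b in self.blocks if b.label == label]

    def sample_mask(self, label: str) -> np.ndarray:
        """Boolean sample mask of the condition's blocks, [onset, end)."""
        mask = np.zeros(self.n_samples, dtype=bool)
        fs = self.sampling_rate
        for b in self.blocks_for(label):
            i0 = int(np.ceil(b.onset * fs - 1e-9))
            i1 = int(np.ceil(b.end * fs - 1e-9))
            mask[i0:min(i1, self.n_samples)] = True
        return mask

    def condition_span(self, label: str) -> tuple[float, float]:
        """(first onset, last end) of the condition in seconds."""
        bs = self.blocks_for(label)
        if not bs:
            raise InvalidParameterError(f"no blocks labeled {label!r}")
        return bs[0].onset, bs[-1].end


@dataclass(frozen=True)
class ProtocolTiming:
    """Rest gaps stitching the conditions into one session."""

    lead_in_s: float = 30.0       # quiet baseline before the first block
    between_sides_s: float = 60.0
    pre_vr_rest_s: float = 120.0  # scripted 2-minute rest before VR
    between_vr_s: float = 30.0
    tail_s: float = 30.0


def make_protocol(
    cycle_params: CycleParams | None = None,
    vr_duration_s: float = 360.0,
    sampling_rate: float = 10.0,
    timing: ProtocolTiming | None = None,
) -> TaskDesign:
    """Build the four-condition session design.

    Movement conditions are represented by their hold sub-blocks (the epochs
    of sustained evoked pain): ``n_cycles`` cycles x 2 holds of ``hold_s``
    each, noninjured side first. Each VR condition is a single
    ``vr_duration_s`` block.
    """
    cp = cycle_params or CycleParams()
    tm = timing or ProtocolTiming()
    if vr_duration_s <= 0:
        raise InvalidParameterError("vr_duration_s must be positive")
    if sampling_rate <= 0:
        raise InvalidParameterError("sampling_rate must be positive")

    blocks: list[Block] = []
    t = tm.lead_in_s
    for side in (CONDITION_NONINJURED, CONDITION_INJURED):
        for _ in range(cp.n_cycles):
            t += cp.move_s
            blocks.append(Block(side, t, cp.hold_s))
            t += cp.hold_s + cp.move_s
            blocks.append(Block(side, t, cp.hold_s))
            t += cp.hold_s + cp.relax_s
        t += tm.between_sides_s if side == CONDITION_NONINJURED else tm.pre_vr_rest_s
    blocks.append(Block(CONDITION_RELAXATION, t, vr_duration_s))
    t += vr_duration_s + tm.between_vr_s
    blocks.append(Block(CONDITION_DISTRACTION, t, vr_duration_s))
    t += vr_duration_s + tm.tail_s
    return TaskDesign(blocks=blocks, sampling_rate=sampling_rate, total_duration=t)
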