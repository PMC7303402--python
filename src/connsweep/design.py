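"""Block-design timing: alternating visual-motion / static-dots blocks.

The experiment shows coherently moving dots for 27.5 s followed by static
dots for 27.5 s, repeated for 12 cycles, scanned with TR 2.45 s for 260
volumes.  Twelve full cycles span 660 s while the analyzed run covers
260 x 2.45 = 637 s, so the final block is truncated (not dropped) at the
end of acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CONDITIONS = ("motion", "static")

#: acquisition defaults
DEFAULT_TR = 2.45
DEFAULT_N_VOLUMES = 260
DEFAULT_BLOCK_DURATION = 27.5
DEFAULT_N_CYCLES = 12


@dataclass(frozen=True)
class Block:
    onset: float       # seconds from run start
    duration: float    # seconds
    condition: str     # "motion" | "static"


@dataclass(frozen=True)
class SessionDesign:
    """Timing of one scanning run."""

    tr: float
    n_volumes: int
    blocks: tuple[Block, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.n_volumes <= 0:
            raise ValueError(f"n_volumes must be positive, got {self.n_volumes}")
        span = self.tr * self.n_volumes
        prev_end = 0.0
        for i, b in enumerate(self.blocks):
            if b.condition not in CONDITIONS:
                raise ValueError(f"block {i}: unknown condition {b.condition!r}")
            if b.duration <= 0:
                raise ValueError(f"block {i}: non-positive duration {b.duration}")
            if b.onset + 1e-9 < prev_end:
                raise ValueError(f"block {i}: overlaps previous block")
            prev_end = b.onset + b.duration
        if prev_end > span + 1e-9:
            raise ValueError(
                f"blocks extend to {prev_end:.2f} s beyond the run span {span:.2f} s"
            )

    @property
    def duration(self) -> float:
        """Run span in seconds (n_volumes x tr)."""
        return self.tr * self.n_volumes

    def blocks_of(self, condition: str) -> tuple[Block, ...]:
        if condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {condition!r}; valid: {CONDITIONS}"
            )
        return tuple(b for b in self.blocks if b.condition == condition)


def make_design(
    tr: float = DEFAULT_TR,
    n_volumes: int = DEFAULT_N_VOLUMES,
    block_duration: float = DEFAULT_BLOCK_DURATION,
    n_cycles: int = DEFAULT_N_CYCLES,
) -> SessionDesign:
    """Alternating motion/static design starting with motion.

    Each cycle is one motion block followed by one static block of equal
    duration.  Blocks that extend past ``n_volumes * tr`` are truncated to
    the run end; blocks that would start at or after it are dropped.
    """
    if tr <= 0 or n_volumes <= 0 or block_duration <= 0 or n_cycles <= 0:
        raise ValueError("tr, n_volumes, block_duration, n_cycles must be positive")
    span = tr * n_volumes
    blocks: list[Block] = []
    t = 0.0
    for _ in range(n_cycles):
        for condition in CONDITIONS:
            if t >= span - 1e-9:
                break
            dur = min(block_duration, span - t)
            blocks.append(Block(onset=t, duration=dur, condition=condition))
            t += block_duration
    return SessionDesign(tr=tr, n_volumes=n_volumes, blocks=tuple(blocks))
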