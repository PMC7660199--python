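"""Chained probe assembly and orthogonal-sequence accounting.

Each target is first tiled by unlabeled 45-nt *pre-decoding* probes
(20-nt target-binding segment + 5T spacer + 20-nt landing segment).  Every
subsequent cycle adds fluorophore-labeled 70-nt *decoding* probes built as

    revcomp(previous landing) + TTTTT + next landing + TTTTT + next landing

so each bound probe presents two identical landing sites and recruits two
probes in the following cycle — the source of the geometric signal
amplification.  One orthogonal 20-nt sequence is consumed per target per
cycle, which is why profiling 30,000 targets over 8 cycles needs a
240,000-sequence orthogonal pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.SeqIO import parse as _fasta_parse

SPACER = "TTTTT"
SEGMENT_LEN = 20
PRE_DECODING_LEN = 45   # 20 + 5 + 20
DECODING_LEN = 70       # 20 + 5 + 20 + 5 + 20

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

__all__ = [
    "PoolExhaustedError",
    "PreDecodingProbe",
    "DecodingProbe",
    "OrthogonalPool",
    "ProbeSeries",
    "reverse_complement",
    "assemble_predecoding",
    "assemble_decoding",
    "build_probe_series",
    "pool_requirement",
    "crosshyb_screen",
    "write_probes_fasta",
    "read_pool",
]


class PoolExhaustedError(RuntimeError):
    """Raised when the orthogonal pool cannot supply another landing."""


def _check_seq(seq: str, length: int | None = None, what: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"{what} is empty")
    if set(seq) - set("ACGT"):
        raise ValueError(f"{what} {seq!r} contains characters outside ACGT")
    if length is not None and len(seq) != length:
        raise ValueError(f"{what} must be {length} nt, got {len(seq)}")
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an uppercase ACGT string."""
    _check_seq(seq)
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PreDecodingProbe:
    """45-nt unlabeled probe: target-binding + 5T + landing."""

    target_binding: str
    landing: str

    @property
    def full_sequence(self) -> str:
        return self.target_binding + SPACER + self.landing


@dataclass(frozen=True)
class DecodingProbe:
    """70-nt labeled probe for one cycle.

    ``prev_binding`` hybridizes to the previous tier's landing;
    the two identical ``next_landing`` copies recruit the next tier.
    """

    cycle_index: int  # 1-based
    prev_binding: str
    next_landing: str
    channel: int

    @property
    def full_sequence(self) -> str:
        return self.prev_binding + SPACER + self.next_landing + SPACER + self.next_landing


@dataclass
class OrthogonalPool:
    """Ordered pool of validated orthogonal 20-nt sequences.

    ``draw`` hands out sequences front to back and tracks consumption so a
    design session can audit how much of the pool an experiment costs.
    """

    sequences: list[str]
    consumed: int = 0

    def __post_init__(self) -> None:
        for s in self.sequences:
            _check_seq(s, SEGMENT_LEN, "pool sequence")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("pool sequences must be unique")

    @property
    def remaining(self) -> int:
        return len(self.sequences) - self.consumed

    def draw(self, n: int = 1) -> list[str]:
        if n > self.remaining:
            raise PoolExhaustedError(
                f"pool has {self.remaining} sequences left, needed {n}"
            )
        out = self.sequences[self.consumed : self.consumed + n]
        self.consumed += n
        return out


@dataclass
class ProbeSeries:
    """All probes for one target: pre-decoding tier plus one probe per cycle."""

    target_id: str
    color_sequence: tuple[int, ...]
    pre_decoding: list[PreDecodingProbe] = field(default_factory=list)
    decoding: list[DecodingProbe] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return len(self.decoding)


def assemble_predecoding(target_binding: str, landing: str) -> PreDecodingProbe:
    """Join a 20-nt target-binding segment and a 20-nt landing with a 5T spacer."""
    _check_seq(target_binding, SEGMENT_LEN, "target_binding")
    _check_seq(landing, SEGMENT_LEN, "landing")
    probe = PreDecodingProbe(target_binding=target_binding, landing=landing)
    assert len(probe.full_sequence) == PRE_DECODING_LEN
    return probe


def assemble_decoding(
    prev_landing: str, next_landing: str, cycle: int, channel: int
) -> DecodingProbe:
    """Build the 70-nt probe that binds ``prev_landing`` and presents two
    copies of ``next_landing``."""
    _check_seq(prev_landing, SEGMENT_LEN, "prev_landing")
    _check_seq(next_landing, SEGMENT_LEN, "next_landing")
    if cycle < 1:
        raise ValueError("cycle is 1-based")
    probe = DecodingProbe(
        cycle_index=cycle,
        prev_binding=reverse_complement(prev_landing),
        next_landing=next_landing,
        channel=channel,
    )
    assert len(probe.full_sequence) == DECODING_LEN
    return probe


def build_probe_series(
    target_id: str,
    color_sequence: Sequence[int],
    target_binding_sites: Iterable[str],
    pool: OrthogonalPool,
) -> ProbeSeries:
    """Assemble the full chained series for one target.

    Draws exactly ``len(color_sequence)`` sequences from the pool — one
    landing per tier, where the draw for cycle ``c`` is the landing the
    cycle-``c`` probe binds (so the cycle-1 draw doubles as the pre-decoding
    landing shared by all of the target's pre-decoding probes).  The final
    cycle's probe keeps the two-landing architecture; since no cycle follows,
    its recruiting segments reuse the tier-0 landing rather than costing an
    extra draw.
    """
    colors = tuple(color_sequence)
    n_cycles = len(colors)
    if n_cycles < 1:
        raise ValueError("color_sequence is empty")
    sites = [
        _check_seq(s, SEGMENT_LEN, "target_binding_site") for s in target_binding_sites
    ]
    if not sites:
        raise ValueError("need at least one target-binding site")

    landings = pool.draw(n_cycles)  # landings[c-1] is what cycle c binds
    pre = [assemble_predecoding(site, landings[0]) for site in sites]
    decoding = []
    for c in range(1, n_cycles + 1):
        next_landing = landings[c] if c < n_cycles else landings[0]
        decoding.append(
            assemble_decoding(
                prev_landing=landings[c - 1],
                next_landing=next_landing,
                cycle=c,
                channel=colors[c - 1],
            )
        )
    return ProbeSeries(
        target_id=target_id,
        color_sequence=colors,
        pre_decoding=pre,
        decoding=decoding,
    )


def pool_requirement(n_targets: int, n_cycles: int) -> int:
    """Orthogonal sequences consumed: one per target per cycle."""
    if n_targets < 1 or n_cycles < 1:
        raise ValueError("counts must be positive")
    return n_targets * n_cycles


def _longest_complementary_run(s1: str, s2: str) -> int:
    """Longest contiguous stretch of s1 that is complementary to s2 at any
    offset = longest common substring of s1 and revcomp(s2)."""
    t = reverse_complement(s2)
    n, m = len(s1), len(t)
    best = 0
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ci = s1[i - 1]
        for j in range(1, m + 1):
            if ci == t[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def crosshyb_screen(
    sequences: Sequence[str], max_run: int = 12
) -> list[tuple[int, int, int]]:
    """Flag sequence pairs with long contiguous complementary runs.

    Returns ``(i, j, run)`` for every ordered pair ``i < j`` whose longest
    contiguous complementary stretch (``sequences[i]`` against the reverse
    complement of ``sequences[j]``, any offset) reaches ``max_run`` bases.
    The default of 12 is a conservative screening cutoff; lower it for
    stricter orthogonality.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences to screen")
    seqs = [_check_seq(s) for s in sequences]
    flagged = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            run = _longest_complementary_run(seqs[i], seqs[j])
            if run >= max_run:
                flagged.append((i, j, run))
    return flagged


def write_probes_fasta(series_list: Iterable[ProbeSeries], path, channel_names=None):
    """Export all probes of the given series as FASTA.

    Record ids follow ``{target}_predec_{k}`` and
    ``{target}_dec_cycle{c}_{channel}``.
    """
    with open(path, "w") as fh:
        for series in series_list:
            for k, p in enumerate(series.pre_decoding, start=1):
                fh.write(f">{series.target_id}_predec_{k}\n{p.full_sequence}\n")
            for d in series.decoding:
                name = (
                    channel_names[d.channel] if channel_names else f"ch{d.channel}"
                )
                fh.write(
                    f">{series.target_id}_dec_cycle{d.cycle_index}_{name}\n"
                    f"{d.full_sequence}\n"
                )


def read_pool(path) -> OrthogonalPool:
    """Load an orthogonal pool from FASTA or one-sequence-per-line text."""
    with open(path) as fh:
        head = fh.read(1)
    if head == ">":
        seqs = [str(rec.seq).upper() for rec in _fasta_parse(path, "fasta")]
    else:
        with open(path) as fh:
            seqs = [line.strip().upper() for line in fh if line.strip()]
    return OrthogonalPool(sequences=seqs)
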