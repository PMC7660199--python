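"""Combinatorial color-sequence codebooks.

In consecutive-hybridization FISH every molecule shows one fluorescence
channel per cycle; the ordered list of channels across cycles (its *color
sequence*) identifies the target.  With ``M`` fluorophores per cycle and
``N`` cycles the code space holds ``M**N`` sequences, so a handful of
cycles covers tens of thousands of targets (2**16 = 65,536; 3**9 = 19,683;
4**8 = 65,536).  No error correction is built into the code: sequences are
used raw, and :func:`min_pairwise_hamming` exists only as a reporting
metric.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Codebook",
    "capacity",
    "generate_codebook",
    "min_pairwise_hamming",
    "read_codebook",
    "write_codebook",
    "default_channel_names",
]

#: Fluorophores used in the demonstrations, in spectral order.
_KNOWN_FLUOROPHORES = ("Alexa488", "Quasar570", "Cy5")


def default_channel_names(n_channels: int) -> list[str]:
    """Human-readable channel names for ``n_channels`` channels.

    Two channels map to Quasar 570 / Cy5 (the RNA demonstrations), three to
    Alexa 488 / Quasar 570 / Cy5 (the DNA demonstration); anything else
    falls back to ``ch0..chK``.
    """
    if n_channels == 2:
        return ["Quasar570", "Cy5"]
    if n_channels == 3:
        return list(_KNOWN_FLUOROPHORES)
    return [f"ch{i}" for i in range(n_channels)]


def capacity(n_channels: int, n_cycles: int) -> int:
    """Number of distinct color sequences: ``n_channels ** n_cycles``.

    Exact integer arithmetic; no overflow at e.g. ``capacity(4, 30)``.
    """
    if n_channels < 1 or n_cycles < 1:
        raise ValueError(
            f"n_channels and n_cycles must be >= 1, got {n_channels}, {n_cycles}"
        )
    return n_channels ** n_cycles


@dataclass
class Codebook:
    """Target -> color-sequence mapping over ``n_channels`` fluorophores.

    ``entries`` maps each target id to a tuple of 0-based channel indices of
    length ``n_cycles``.  ``channel_names`` translates indices to fluorophore
    labels for reports and CSV round-trips.
    """

    n_channels: int
    n_cycles: int
    entries: dict[str, tuple[int, ...]]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.channel_names:
            self.channel_names = default_channel_names(self.n_channels)
        self.validate()

    def validate(self) -> None:
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.n_channels} channels"
            )
        if len(self.entries) > capacity(self.n_channels, self.n_cycles):
            raise ValueError("more entries than the code space holds")
        seen: dict[tuple[int, ...], str] = {}
        for target, seq in self.entries.items():
            seq = tuple(seq)
            if len(seq) != self.n_cycles:
                raise ValueError(
                    f"sequence for {target!r} has length {len(seq)}, "
                    f"expected {self.n_cycles}"
                )
            if any((c < 0 or c >= self.n_channels) for c in seq):
                raise ValueError(f"sequence for {target!r} has an invalid channel")
            if seq in seen:
                raise ValueError(
                    f"targets {seen[seq]!r} and {target!r} share color sequence {seq}"
                )
            seen[seq] = target

    @property
    def targets(self) -> list[str]:
        return list(self.entries)

    def sequence_of(self, target_id: str) -> tuple[int, ...]:
        return tuple(self.entries[target_id])

    def lookup(self, sequence: Sequence[int]) -> str | None:
        """Target whose color sequence equals ``sequence``, or None."""
        key = tuple(sequence)
        for target, seq in self.entries.items():
            if tuple(seq) == key:
                return target
        return None

    def named_sequence(self, target_id: str) -> list[str]:
        return [self.channel_names[c] for c in self.entries[target_id]]

    @classmethod
    def from_entries(
        cls,
        entries: Mapping[str, Sequence[int]],
        n_channels: int,
        n_cycles: int,
        channel_names: Sequence[str] | None = None,
    ) -> "Codebook":
        """Build a codebook from an explicit target -> sequence table."""
        return cls(
            n_channels=n_channels,
            n_cycles=n_cycles,
            entries={t: tuple(s) for t, s in entries.items()},
            channel_names=list(channel_names) if channel_names else [],
        )


def generate_codebook(
    n_channels: int,
    n_cycles: int,
    target_ids: Iterable[str],
    channel_names: Sequence[str] | None = None,
) -> Codebook:
    """Assign color sequences to targets deterministically.

    Sequences are enumerated in lexicographic order and handed to targets in
    their input order; use :meth:`Codebook.from_entries` when a specific
    scheme (e.g. the two-gene alternating design) is required instead.
    """
    targets = list(target_ids)
    if len(set(targets)) != len(targets):
        raise ValueError("duplicate target ids")
    cap = capacity(n_channels, n_cycles)
    if len(targets) > cap:
        raise ValueError(
            f"{len(targets)} targets exceed capacity {cap} "
            f"({n_channels} channels, {n_cycles} cycles)"
        )
    seqs = itertools.product(range(n_channels), repeat=n_cycles)
    entries = {t: seq for t, seq in zip(targets, seqs)}
    return Codebook(
        n_channels=n_channels,
        n_cycles=n_cycles,
        entries=entries,
        channel_names=list(channel_names) if channel_names else [],
    )


def min_pairwise_hamming(codebook: Codebook) -> int:
    """Minimum Hamming distance over all pairs of entries (reporting only)."""
    seqs = [tuple(s) for s in codebook.entries.values()]
    if len(seqs) < 2:
        raise ValueError("need at least 2 entries")
    best = codebook.n_cycles
    for a, b in itertools.combinations(seqs, 2):
        d = sum(x != y for x, y in zip(a, b))
        if d < best:
            best = d
            if best == 0:  # pragma: no cover - invariant forbids this
                break
    return best


def write_codebook(codebook: Codebook, path) -> None:
    """Write CSV with columns target_id, cycle_1..cycle_N (channel names)."""
    rows = []
    for target, seq in codebook.entries.items():
        row = {"target_id": target}
        for c, ch in enumerate(seq, start=1):
            row[f"cycle_{c}"] = codebook.channel_names[ch]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_codebook(path, channel_names: Sequence[str] | None = None) -> Codebook:
    """Read a codebook CSV written by :func:`write_codebook`.

    Channel names default to the sorted set observed in the table unless
    given explicitly (order defines the channel indexing).
    """
    df = pd.read_csv(path, dtype=str)
    if "target_id" not in df.columns:
        raise ValueError("codebook CSV needs a target_id column")
    cycle_cols = sorted(
        (c for c in df.columns if c.startswith("cycle_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not cycle_cols:
        raise ValueError("codebook CSV needs cycle_1..cycle_N columns")
    observed = pd.unique(df[cycle_cols].values.ravel())
    if channel_names is None:
        known = [n for n in _KNOWN_FLUOROPHORES if n in observed]
        extra = sorted(set(observed) - set(known))
        channel_names = known + extra
    index = {name: i for i, name in enumerate(channel_names)}
    entries = {}
    for _, row in df.iterrows():
        try:
            entries[row["target_id"]] = tuple(index[row[c]] for c in cycle_cols)
        except KeyError as err:
            raise ValueError(f"unknown channel name {err} in codebook CSV") from err
    return Codebook(
        n_channels=len(channel_names),
        n_cycles=len(cycle_cols),
        entries=entries,
        channel_names=list(channel_names),
    )
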