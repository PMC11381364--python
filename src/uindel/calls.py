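"""Per-read editing-site alignment, state calling, and population aggregation.

A *standard* read is one whose non-U sequence equals the template backbone
exactly: such a read aligns to the ES system unambiguously and its per-ES U
counts are simply the U run lengths between consecutive backbone characters.
Reads with any non-U mismatch (substitutions, non-U indels, partial length)
are *nonstandard* and are counted but excluded from all statistics.

Per-ES states compare the read's U count with the two template states:

========== ==========================================
canonical  matches the fully edited count (and the site is informative)
pre        matches the pre-edited count (and the site is informative)
shared     the site is uninformative (u_pre == u_full) and the read matches
noncanonical  matches neither template state
========== ==========================================

The *editing stop site* is the 5'-most ES terminating the contiguous run of
canonical(-compatible) editing anchored at ES 1; mis-edited sequence 5' of it
is a *junction*, whose length is measured in ES units as the span from the
stop site to the 5'-most ES that matches neither pre-compatible state.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from .errors import EmptyInput, EmptyPopulation, NotStandard
from .template import TemplatePair, canonicalize, synthesize, u_profile

#: Junction-length bins (inclusive edges): 0, 1-10, 11-20, >20 ES.
JL_BIN_LABELS = ("0", "1-10", "11-20", ">20")


def jl_bin_index(jl: int) -> int:
    """Map a junction length in ES units onto the four standard bins."""
    if jl == 0:
        return 0
    if jl <= 10:
        return 1
    if jl <= 20:
        return 2
    return 3


STATE_CANONICAL = "canonical"
STATE_PRE = "pre"
STATE_SHARED = "shared"
STATE_NONCANONICAL = "noncanonical"


@dataclass
class ReadCall:
    """One read's alignment to the ES system and derived editing metrics."""

    read_id: str
    standard: bool
    u_counts: np.ndarray | None = None  # ES-indexed (index 0 = ES 1)
    states: list[str] | None = None
    stop_site: int | None = None
    junction_length: int | None = None
    fully_edited: bool | None = None
    u5: int = 0
    u3: int = 0
    count: int = 1


def trim_primers(seq: str, five_prime: str | None, three_prime: str | None) -> str:
    """Strip exact-match primer anchors from the ends of a read, if present."""
    seq = canonicalize(seq)
    if five_prime:
        p = canonicalize(five_prime)
        if seq.startswith(p):
            seq = seq[len(p):]
    if three_prime:
        p = canonicalize(three_prime)
        if seq.endswith(p):
            seq = seq[: len(seq) - len(p)]
    return seq


def classify_read(read: str, pair: TemplatePair) -> str:
    """Return ``"standard"`` iff the read's U-stripped sequence equals the backbone."""
    seq = canonicalize(read)
    backbone = "".join(c for c in seq if c != "U")
    return "standard" if backbone == pair.backbone else "nonstandard"


def align_read(read: str, pair: TemplatePair) -> np.ndarray:
    """Per-ES U counts of a standard read (ES-indexed, ES 1 first).

    Raises :class:`NotStandard` if the read's backbone differs from the
    template's.
    """
    seq = canonicalize(read)
    _, gaps, _, backbone = u_profile(seq)
    if backbone != pair.backbone:
        raise NotStandard("read backbone does not match template backbone")
    return np.asarray(gaps[::-1], dtype=np.int64)


def es_states(u_counts: np.ndarray, pair: TemplatePair) -> list[str]:
    """State of every ES given a read's U counts (see module docstring)."""
    states = []
    for u, up, uf in zip(u_counts, pair.u_pre, pair.u_full):
        if up == uf:
            states.append(STATE_SHARED if u == up else STATE_NONCANONICAL)
        elif u == uf:
            states.append(STATE_CANONICAL)
        elif u == up:
            states.append(STATE_PRE)
        else:
            states.append(STATE_NONCANONICAL)
    return states


def _stop_and_junction(states: list[str]) -> tuple[int, int]:
    """Editing stop site and junction length from per-ES states.

    Shared sites extend a canonical run and never open a junction: they carry
    no information about editing progression, so both the stop run (which
    needs canonical-compatible states) and the junction test (which needs
    pre-compatible states) accept them.
    """
    n = len(states)
    stop = 0
    while stop < n and states[stop] in (STATE_CANONICAL, STATE_SHARED):
        stop += 1
    # 5'-most ES (largest index) not pre-compatible marks the junction end.
    jl = 0
    for i in range(n - 1, stop - 1, -1):
        if states[i] not in (STATE_PRE, STATE_SHARED):
            jl = (i + 1) - stop
            break
    return stop, jl


def call_read(read: str, pair: TemplatePair, read_id: str = "read", count: int = 1) -> ReadCall:
    """Full per-read call: standard flag, U counts, states, stop site, JL."""
    seq = canonicalize(read)
    u5, gaps, u3, backbone = u_profile(seq)
    if backbone != pair.backbone:
        return ReadCall(read_id=read_id, standard=False, count=count)
    u_counts = np.asarray(gaps[::-1], dtype=np.int64)
    states = es_states(u_counts, pair)
    stop, jl = _stop_and_junction(states)
    return ReadCall(
        read_id=read_id,
        standard=True,
        u_counts=u_counts,
        states=states,
        stop_site=stop,
        junction_length=jl,
        fully_edited=stop >= pair.max_es,
        u5=u5,
        u3=u3,
        count=count,
    )


def reconstruct(call: ReadCall, pair: TemplatePair) -> str:
    """Rebuild the read sequence of a standard call (round-trip check)."""
    if not call.standard:
        raise NotStandard("cannot reconstruct a nonstandard read")
    return synthesize(pair.backbone, call.u_counts, call.u5, call.u3)


@dataclass
class SamplePopulation:
    """A replicate's read calls aggregated per stop site and JL bin.

    ``stop_counts_raw[s]`` counts standard reads with editing stop site ``s``
    (s = 0: no canonical editing anchored at ES 1; s = n_es: canonical to the
    5' end).  ``jl_bins[s, b]`` splits each stop site's reads over the four
    junction-length bins.  ``stop_counts_norm`` is filled by
    :func:`uindel.stats.normalize_counts`.
    """

    sample_id: str
    condition: str  # "induced" | "control"
    n_es: int
    stop_counts_raw: np.ndarray  # shape (n_es + 1,)
    jl_bins: np.ndarray  # shape (n_es + 1, 4)
    total_standard: int
    total_nonstandard: int
    stop_counts_norm: np.ndarray | None = None
    norm_total: float | None = None

    def __post_init__(self) -> None:
        self.stop_counts_raw = np.asarray(self.stop_counts_raw, dtype=np.int64)
        self.jl_bins = np.asarray(self.jl_bins, dtype=np.int64)


def aggregate_population(
    reads: Iterable[tuple[str, str, int]] | Iterable[str],
    pair: TemplatePair,
    sample_id: str = "sample",
    condition: str = "control",
    five_prime_primer: str | None = None,
    three_prime_primer: str | None = None,
) -> SamplePopulation:
    """Call every read and tally stop sites and junction-length bins.

    ``reads`` yields either bare sequences or ``(read_id, sequence, count)``
    triples; duplicate sequences are collapsed first so each unique sequence
    is aligned once.  Nonstandard reads are counted and excluded from every
    downstream tally.
    """
    counter: Counter[str] = Counter()
    for item in reads:
        if isinstance(item, str):
            counter[item] += 1
        else:
            _, seq, count = item
            counter[seq] += int(count)
    if not counter:
        raise EmptyInput("read population is empty")

    n_rows = pair.n_es + 1
    stop_counts = np.zeros(n_rows, dtype=np.int64)
    jl_bins = np.zeros((n_rows, 4), dtype=np.int64)
    total_standard = 0
    total_nonstandard = 0
    for seq, count in counter.items():
        s = seq
        if five_prime_primer or three_prime_primer:
            s = trim_primers(canonicalize(s), five_prime_primer, three_prime_primer)
        call = call_read(s, pair, count=count)
        if call.standard:
            stop_counts[call.stop_site] += count
            jl_bins[call.stop_site, jl_bin_index(call.junction_length)] += count
            total_standard += count
        else:
            total_nonstandard += count
    if total_standard == 0:
        warnings.warn(
            f"sample {sample_id!r}: all {total_nonstandard} reads are nonstandard",
            stacklevel=2,
        )
    return SamplePopulation(
        sample_id=sample_id,
        condition=condition,
        n_es=pair.n_es,
        stop_counts_raw=stop_counts,
        jl_bins=jl_bins,
        total_standard=total_standard,
        total_nonstandard=total_nonstandard,
    )


def iter_fasta_reads(path) -> Iterator[tuple[str, str, int]]:
    """Yield ``(read_id, sequence, count)`` from a population FASTA.

    Multiplicity is carried either by duplicate records or by a ``;count=N``
    suffix on the record id.
    """
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        count = 1
        if ";count=" in rid:
            rid, _, tail = rid.partition(";count=")
            count = int(tail)
        yield rid, str(rec.seq), count


def population_from_fasta(
    path,
    pair: TemplatePair,
    sample_id: str | None = None,
    condition: str = "control",
    **kwargs,
) -> SamplePopulation:
    """Aggregate a FASTA read population against a template pair."""
    import os

    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(str(path)))[0]
    return aggregate_population(
        iter_fasta_reads(path), pair, sample_id=sample_id, condition=condition, **kwargs
    )
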