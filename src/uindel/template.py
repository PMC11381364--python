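"""Editing-site coordinate system built from a pre-edited / fully edited template pair.

Kinetoplastid U-indel editing inserts and deletes uridines without touching the
other nucleotides, so the pre-edited and the canonically (fully) edited form of
a transcript share an identical non-U *backbone* and differ only in how many Us
sit in each gap between adjacent backbone characters.  Each interior gap is an
*editing site* (ES).  ESs are numbered 3'->5' (ES 1 is the 3'-most gap), the
direction in which editing progresses.

Terminal U runs (before the first or after the last non-U character) have only
one non-U neighbour, hence are not editing sites; they are carried separately
and excluded from all statistics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    BackboneMismatch,
    DegenerateTemplate,
    IndexOutOfRange,
    InvalidAlphabet,
)

_VALID = re.compile(r"^[ACGTU]+$")

#: T (sequencing output) and U (RNA) are the same symbol internally.
_CANON = str.maketrans({"T": "U"})


def canonicalize(seq: str) -> str:
    """Uppercase and map T->U; raise :class:`InvalidAlphabet` on anything else."""
    s = str(seq).strip().upper().translate(_CANON)
    if not s or not _VALID.match(s):
        bad = sorted(set(s) - set("ACGTU")) if s else ["<empty>"]
        raise InvalidAlphabet(f"sequence contains invalid characters: {bad}")
    return s


def u_profile(seq: str) -> tuple[int, list[int], int, str]:
    """Decompose a canonicalized sequence into U runs around its backbone.

    Returns ``(u5, gaps, u3, backbone)`` where ``gaps`` lists the U-run length
    in every interior gap in 5'->3' backbone order (length = len(backbone)-1),
    and ``u5`` / ``u3`` are the terminal U runs.
    """
    backbone_chars = [c for c in seq if c != "U"]
    backbone = "".join(backbone_chars)
    if not backbone:
        # all-U sequence: no backbone at all
        return len(seq), [], 0, ""
    runs: list[int] = []
    current = 0
    pre5 = 0
    seen_backbone = False
    for c in seq:
        if c == "U":
            current += 1
        else:
            if seen_backbone:
                runs.append(current)
            else:
                pre5 = current
                seen_backbone = True
            current = 0
    return pre5, runs, current, backbone


def _gaps_to_es(gaps: list[int]) -> np.ndarray:
    """Interior gaps in 5'->3' order -> ES-indexed vector (ES 1 = 3'-most gap)."""
    return np.asarray(gaps[::-1], dtype=np.int64)


def synthesize(
    backbone: str, u_counts: np.ndarray, u5: int = 0, u3: int = 0
) -> str:
    """Re-interleave per-ES U counts (ES-indexed) into the backbone.

    Inverse of :func:`u_profile` composed with :func:`_gaps_to_es`.
    """
    n_es = len(backbone) - 1
    gaps = np.asarray(u_counts, dtype=np.int64)[::-1]  # back to 5'->3' gap order
    if len(gaps) != n_es:
        raise ValueError(f"u_counts length {len(gaps)} != n_es {n_es}")
    parts = ["U" * u5, backbone[0]]
    for j in range(n_es):
        parts.append("U" * int(gaps[j]))
        parts.append(backbone[j + 1])
    parts.append("U" * u3)
    return "".join(parts)


@dataclass(frozen=True)
class TemplatePair:
    """The shared non-U backbone plus per-ES U counts of both editing states.

    Attributes
    ----------
    backbone
        5'->3' sequence over {A, C, G} with every U removed.
    u_pre, u_full
        U count at each ES (index 0 holds ES 1, the 3'-most site) in the
        pre-edited and fully edited sequence respectively.
    u5_pre, u3_pre, u5_full, u3_full
        Terminal U runs of each input sequence; not editing sites.
    max_es
        ES index at which "fully edited" is declared.  Defaults to n_es; a
        smaller value implements 5'-truncation conventions where the canonical
        sequence is only trusted up to a given ES (as used for amplicons whose
        5' end suffers sequencing discrepancies).
    """

    backbone: str
    u_pre: np.ndarray
    u_full: np.ndarray
    u5_pre: int = 0
    u3_pre: int = 0
    u5_full: int = 0
    u3_full: int = 0
    max_es: int | None = None

    n_es: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_es", len(self.backbone) - 1)
        object.__setattr__(
            self, "u_pre", np.asarray(self.u_pre, dtype=np.int64)
        )
        object.__setattr__(
            self, "u_full", np.asarray(self.u_full, dtype=np.int64)
        )
        if self.max_es is None:
            object.__setattr__(self, "max_es", self.n_es)
        if not 1 <= self.max_es <= self.n_es:
            raise IndexOutOfRange(
                f"max_es {self.max_es} outside 1..{self.n_es}"
            )

    # -- derived views -------------------------------------------------

    @property
    def pre_edited(self) -> str:
        return synthesize(self.backbone, self.u_pre, self.u5_pre, self.u3_pre)

    @property
    def fully_edited(self) -> str:
        return synthesize(
            self.backbone, self.u_full, self.u5_full, self.u3_full
        )

    def site_class(self, es: int) -> str:
        """Classify ES ``es`` as ``insertion``, ``deletion`` or ``shared``.

        Insertion sites gain Us during editing (u_full > u_pre), deletion
        sites lose encoded Us (u_full < u_pre), shared sites are identical in
        both states and carry no information about editing progression.
        """
        if not 1 <= es <= self.n_es:
            raise IndexOutOfRange(f"ES {es} outside 1..{self.n_es}")
        pre, full = int(self.u_pre[es - 1]), int(self.u_full[es - 1])
        if full > pre:
            return "insertion"
        if full < pre:
            return "deletion"
        return "shared"

    def site_classes(self) -> list[str]:
        return [self.site_class(e) for e in range(1, self.n_es + 1)]

    def to_frame(self) -> pd.DataFrame:
        """Per-ES map: ES index, 5'->3' backbone gap position, U counts, class."""
        es = np.arange(1, self.n_es + 1)
        return pd.DataFrame(
            {
                "es": es,
                # gap j (between backbone chars j and j+1, 1-based, 5'->3')
                "backbone_pos_5to3": self.n_es - es + 1,
                "u_pre": self.u_pre,
                "u_full": self.u_full,
                "site_class": self.site_classes(),
            }
        )


def build_template_pair(
    pre_edited: str, fully_edited: str, max_es: int | None = None
) -> TemplatePair:
    """Align a pre-edited / fully edited sequence pair into one ES system.

    Both sequences are canonicalized (case-insensitive, T==U); they must share
    an identical non-U backbone, which defines ``n_es = len(backbone) - 1``
    editing sites, and must differ at at least one ES.

    Raises
    ------
    BackboneMismatch
        if the U-stripped sequences differ (no common ES system exists).
    DegenerateTemplate
        if per-ES U counts are identical everywhere.
    InvalidAlphabet
        for characters outside {A, C, G, T, U}.
    """
    pre = canonicalize(pre_edited)
    full = canonicalize(fully_edited)
    u5p, gaps_p, u3p, bb_p = u_profile(pre)
    u5f, gaps_f, u3f, bb_f = u_profile(full)
    if bb_p != bb_f:
        raise BackboneMismatch(
            f"U-stripped sequences differ: {bb_p!r} vs {bb_f!r}"
        )
    if len(bb_p) < 2:
        raise DegenerateTemplate(
            "backbone shorter than 2 nt defines no editing site"
        )
    u_pre = _gaps_to_es(gaps_p)
    u_full = _gaps_to_es(gaps_f)
    if np.array_equal(u_pre, u_full):
        raise DegenerateTemplate(
            "pre-edited and fully edited sequences agree at every ES"
        )
    return TemplatePair(
        backbone=bb_p,
        u_pre=u_pre,
        u_full=u_full,
        u5_pre=u5p,
        u3_pre=u3p,
        u5_full=u5f,
        u3_full=u3f,
        max_es=max_es,
    )


def site_class(pair: TemplatePair, es: int) -> str:
    """Functional alias for :meth:`TemplatePair.site_class`."""
    return pair.site_class(es)


def read_template_fasta(
    path,
    pre_name: str = "pre_edited",
    full_name: str = "fully_edited",
    max_es: int | None = None,
) -> TemplatePair:
    """Load a template pair from a two-record FASTA (order-insensitive)."""
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    missing = {pre_name, full_name} - set(records)
    if missing:
        raise ValueError(
            f"template FASTA {path} lacks record(s) {sorted(missing)}; "
            f"found {sorted(records)}"
        )
    return build_template_pair(
        records[pre_name], records[full_name], max_es=max_es
    )
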