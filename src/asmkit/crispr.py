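"""Classification of Cas9-edited amplicons against a reference sequence.

Each sequenced colony is aligned globally to the unedited reference
(affine gap penalties: match +1, mismatch -1, gap open -5, gap extend
-1); the net indel size (inserted minus deleted bases) classifies the
colony as deletion, insertion, or unedited, and a frameshift is called
when |net| mod 3 != 0.  Cohort summaries report counts and
nearest-integer percentages per type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = ["AmpliconCall", "EditSummary", "call_indel", "summarize_edits"]

_VALID = set("ACGTN")
_MAX_COOPTIMAL = 64  # bounded enumeration for the leftmost-gap convention


@dataclass
class AmpliconCall:
    """Indel classification of one colony amplicon."""

    colony_id: str
    edit_type: str              # "none" | "deletion" | "insertion"
    net_size: int               # bp, signed (insertions positive)
    frameshift: bool
    distance_to_cut: int | None  # bp from cut site to nearest gap boundary
    ambiguous: bool = False      # co-optimal alignments disagreed on placement
    compound: bool = False       # both insertions and deletions present

    def __post_init__(self) -> None:
        if self.edit_type not in ("none", "deletion", "insertion"):
            raise ValueError(f"unknown edit_type {self.edit_type!r}")
        if self.edit_type == "none" and (self.net_size != 0 or self.frameshift):
            raise ValueError("unedited call must have net_size 0 and no frameshift")
        if self.edit_type != "none" and self.frameshift != (abs(self.net_size) % 3 != 0):
            raise ValueError("frameshift flag inconsistent with net_size")


@dataclass
class EditSummary:
    """Cohort-level indel tally with nearest-integer percentages."""

    n_total: int
    n_deletion: int
    n_insertion: int
    n_none: int
    pct_deletion: int
    pct_insertion: int
    n_frameshift: int

    def summary(self) -> str:
        return "\n".join([
            f"Colonies sequenced : {self.n_total}",
            f"  deletions  : {self.n_deletion} ({self.pct_deletion}%)",
            f"  insertions : {self.n_insertion} ({self.pct_insertion}%)",
            f"  unedited   : {self.n_none}",
            f"  frameshift : {self.n_frameshift}",
        ])


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner


def _check_seq(seq: str, name: str) -> str:
    s = str(seq).upper()
    if not s or set(s) - _VALID:
        raise ValueError(f"{name} must be a non-empty sequence over A/C/G/T/N")
    return s


def _gap_events(alignment) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(deletions, insertions) as (ref_position, length) lists.

    Deletions are reference segments skipped in the amplicon; insertions
    are amplicon segments absent from the reference, anchored at the
    reference coordinate where they occur.
    """
    ref_blocks, amp_blocks = alignment.aligned
    deletions, insertions = [], []
    prev_r_end = prev_a_end = None
    for (r0, r1), (a0, a1) in zip(ref_blocks, amp_blocks):
        if prev_r_end is not None:
            if r0 > prev_r_end:
                deletions.append((prev_r_end, r0 - prev_r_end))
            if a0 > prev_a_end:
                insertions.append((prev_r_end, a0 - prev_a_end))
        prev_r_end, prev_a_end = r1, a1
    return deletions, insertions


def call_indel(reference: str, amplicon: str, cut_site: int,
               colony_id: str = "") -> AmpliconCall:
    """Classify one amplicon's edit relative to the reference.

    Global affine alignment; among co-optimal alignments the one with the
    lexicographically smallest gap-start coordinates is used (leftmost-gap
    convention, as in variant normalization) and the call is flagged
    ambiguous when more than one co-optimal placement exists.  Terminal
    gaps count like internal ones: the synthetic amplicons in scope share
    both ends with the reference.
    """
    ref = _check_seq(reference, "reference")
    amp = _check_seq(amplicon, "amplicon")
    if not 0 <= cut_site < len(ref):
        raise ValueError("cut_site must lie within the reference")

    alignments = _make_aligner().align(ref, amp)
    best, best_key = None, None
    n_seen = 0
    for aln in alignments:
        n_seen += 1
        dels, inss = _gap_events(aln)
        key = tuple(sorted(p for p, _ in dels + inss))
        if best_key is None or key < best_key:
            best, best_key = (dels, inss), key
        if n_seen >= _MAX_COOPTIMAL:
            logger.warning("colony %s: co-optimal alignment enumeration capped "
                           "at %d", colony_id, _MAX_COOPTIMAL)
            break
    dels, inss = best
    ambiguous = n_seen > 1
    if ambiguous:
        logger.info("colony %s: %d co-optimal alignments; leftmost-gap "
                    "placement applied", colony_id, n_seen)

    n_del = sum(length for _, length in dels)
    n_ins = sum(length for _, length in inss)
    net = n_ins - n_del
    has_gaps = bool(dels or inss)
    if net > 0:
        edit_type = "insertion"
    elif net < 0:
        edit_type = "deletion"
    else:
        edit_type = "none"
        if has_gaps:
            logger.info("colony %s: balanced compound edit (net 0) classified "
                        "as none", colony_id)
    compound = bool(dels) and bool(inss)
    if compound and edit_type != "none":
        logger.info("colony %s: compound edit; net change %+d takes type %s",
                    colony_id, net, edit_type)

    if has_gaps:
        boundaries = [p for p, length in dels for p in (p, p + length)]
        boundaries += [p for p, _ in inss]
        distance = min(abs(b - cut_site) for b in boundaries)
    else:
        distance = None

    return AmpliconCall(
        colony_id=colony_id,
        edit_type=edit_type,
        net_size=net if edit_type != "none" else 0,
        frameshift=bool(edit_type != "none" and abs(net) % 3 != 0),
        distance_to_cut=distance,
        ambiguous=ambiguous,
        compound=compound,
    )


def call_indels(reference: str, amplicons: list[tuple[str, str]],
                cut_site: int) -> list[AmpliconCall]:
    """Vector form of :func:`call_indel` over (colony_id, sequence) pairs."""
    return [call_indel(reference, seq, cut_site, colony_id=cid)
            for cid, seq in amplicons]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def summarize_edits(calls: list[AmpliconCall]) -> EditSummary:
    """Tally a cohort of colony calls with nearest-integer percentages."""
    if not calls:
        raise ValueError("no calls to summarize")
    n = len(calls)
    n_del = sum(c.edit_type == "deletion" for c in calls)
    n_ins = sum(c.edit_type == "insertion" for c in calls)
    n_none = n - n_del - n_ins
    return EditSummary(
        n_total=n,
        n_deletion=n_del,
        n_insertion=n_ins,
        n_none=n_none,
        pct_deletion=round(100.0 * n_del / n),
        pct_insertion=round(100.0 * n_ins / n),
        n_frameshift=sum(c.frameshift for c in calls),
    )


def calls_to_frame(calls: list[AmpliconCall]) -> pd.DataFrame:
    """Tabular view of a list of calls."""
    return pd.DataFrame([{
        "colony_id": c.colony_id, "edit_type": c.edit_type,
        "net_size": c.net_size, "frameshift": c.frameshift,
        "distance_to_cut": c.distance_to_cut, "ambiguous": c.ambiguous,
        "compound": c.compound,
    } for c in calls])
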