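"""Exhaustive small-genome read mapping under the classic bowtie
``-v 2 --best --strata -k 50`` policy.

Every (position, strand) pair of the genome is scanned with Hamming
distance (``-v`` semantics: mismatches only, no indels, counted over the
whole tag; 'N' in tag or genome never matches).  Hits within
``max_mismatches`` form the candidate set; only the best stratum (the
minimum observed mismatch count) is reported, and a tag whose candidate
set exceeds ``max_loci`` is suppressed entirely — it contributes no
alignments.  An import path for externally produced SAM re-applies the
same policy so downstream behaviour is identical.

This is a policy re-implementation for desk-scale genomes (~100 kb), not
an indexed aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .collapse import UniTag

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Base codes: N (tag) and N (genome) get distinct non-matching codes so an
# N never matches anything, including another N.
_TAG_CODE = {"A": 1, "C": 2, "G": 3, "T": 4, "N": 5}
_GENOME_CODE = {"A": 1, "C": 2, "G": 3, "T": 4, "N": 6}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignPolicy:
    max_mismatches: int = 2
    best_stratum_only: bool = True
    max_loci: int = 50
    cap_post_stratum: bool = False  # evaluate the >max_loci cap after stratum filtering


@dataclass(frozen=True)
class AlignmentHit:
    sequence: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    mismatches: int


def _encode(seq: str, table: dict[str, int]) -> np.ndarray:
    return np.array([table.get(b, 7) for b in seq], dtype=np.uint8)


class GenomeAligner:
    """Holds encoded chromosomes and maps tags against both strands."""

    def __init__(self, genome: dict[str, str], policy: AlignPolicy | None = None):
        self.policy = policy or AlignPolicy()
        self._chroms = {name: _encode(seq, _GENOME_CODE) for name, seq in genome.items()}

    def align(self, tag: UniTag | str, policy: AlignPolicy | None = None) -> list[AlignmentHit]:
        """All best-stratum hits of a tag, or ``[]`` if unmapped/suppressed."""
        policy = policy or self.policy
        seq = tag.sequence if isinstance(tag, UniTag) else tag
        L = len(seq)
        fwd = _encode(seq, _TAG_CODE)
        rev = _encode(reverse_complement(seq), _TAG_CODE)
        hits: list[AlignmentHit] = []
        for chrom in sorted(self._chroms):
            garr = self._chroms[chrom]
            if L > garr.size:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(garr, L)
            for strand, query in (("+", fwd), ("-", rev)):
                mm = np.count_nonzero(windows != query, axis=1)
                for pos in np.flatnonzero(mm <= policy.max_mismatches):
                    hits.append(
                        AlignmentHit(seq, chrom, int(pos), int(pos) + L, strand, int(mm[pos]))
                    )
        return apply_policy(hits, policy)


def apply_policy(hits: list[AlignmentHit], policy: AlignPolicy) -> list[AlignmentHit]:
    """Best-stratum filtering and the multi-locus suppression cap."""
    hits = [h for h in hits if h.mismatches <= policy.max_mismatches]
    if not hits:
        return []
    if not policy.cap_post_stratum and len(hits) > policy.max_loci:
        return []
    if policy.best_stratum_only:
        best = min(h.mismatches for h in hits)
        hits = [h for h in hits if h.mismatches == best]
    if policy.cap_post_stratum and len(hits) > policy.max_loci:
        return []
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def align_tags(
    tags: Iterable[UniTag],
    genome: dict[str, str],
    policy: AlignPolicy | None = None,
) -> dict[str, list[AlignmentHit]]:
    """Map each tag; tags with no surviving hit map to an empty list."""
    aligner = GenomeAligner(genome, policy)
    return {
        (t.sequence if isinstance(t, UniTag) else t): aligner.align(t) for t in tags
    }


def import_sam(path: str | Path, policy: AlignPolicy | None = None) -> dict[str, list[AlignmentHit]]:
    """Import alignments from SAM and re-apply the stratum/cap policy.

    Mismatch counts come from the ``NM`` tag; a mapped record without one
    aborts, naming the record.  Hits are grouped by read sequence (reverse
    complemented back to the read's original orientation for minus-strand
    records) so the result keys match UniTag sequences.
    """
    policy = policy or AlignPolicy()
    raw: dict[str, list[AlignmentHit]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if not rec.has_tag("NM"):
                raise ValueError(f"SAM record {rec.query_name!r} lacks an NM tag")
            seq = rec.query_sequence
            if seq is None:
                raise ValueError(f"SAM record {rec.query_name!r} lacks a sequence")
            seq = seq.upper()
            strand = "-" if rec.is_reverse else "+"
            if rec.is_reverse:
                seq = reverse_complement(seq)
            hit = AlignmentHit(
                seq,
                rec.reference_name,
                rec.reference_start,
                rec.reference_start + len(seq),
                strand,
                int(rec.get_tag("NM")),
            )
            raw.setdefault(seq, []).append(hit)
    return {seq: apply_policy(hits, policy) for seq, hits in raw.items()}


def write_alignments_tsv(
    hits_by_tag: dict[str, list[AlignmentHit]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("tag\tchrom\tstart\tend\tstrand\tmismatches\n")
        for seq in sorted(hits_by_tag):
            for h in hits_by_tag[seq]:
                fh.write(f"{seq}\t{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t{h.mismatches}\n")
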