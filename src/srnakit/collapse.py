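"""UniTag summarisation: collapse identical read sequences across
libraries and remove dataset-wide singletons before mapping."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .io import ReadRecord


@dataclass
class UniTag:
    """A distinct read sequence with per-library counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


def collapse(
    reads_by_library: Mapping[str, Iterable[ReadRecord | str]],
    remove_singletons: bool = True,
) -> tuple[list[UniTag], int]:
    """Collapse reads to UniTags with per-library counts.

    Singleton removal is dataset-wide: a sequence observed exactly once in
    the whole experiment is dropped.  Returns ``(tags, singleton_reads)``;
    conservation holds as ``sum(tag totals) + singleton_reads == input reads``.
    """
    per_lib: dict[str, Counter] = {}
    totals: Counter = Counter()
    for lib, reads in reads_by_library.items():
        c = Counter(
            r.sequence if isinstance(r, ReadRecord) else r for r in reads
        )
        per_lib[lib] = c
        totals.update(c)

    libraries = list(per_lib)
    tags: list[UniTag] = []
    singleton_reads = 0
    for seq in sorted(totals):
        if remove_singletons and totals[seq] == 1:
            singleton_reads += 1
            continue
        counts = {lib: per_lib[lib][seq] for lib in libraries if per_lib[lib][seq]}
        tags.append(UniTag(seq, counts))
    return tags, singleton_reads


def write_tags_fasta(tags: Iterable[UniTag], path: str | Path) -> None:
    """Serialise tags as FASTA with ``>tag<i>_<total>`` headers."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags, start=1):
            fh.write(f">tag{i}_{tag.total_count}\n{tag.sequence}\n")


def write_tag_counts(tags: list[UniTag], libraries: list[str], path: str | Path) -> None:
    """Per-library tag count TSV (rows: sequences; columns: libraries)."""
    with open(path, "w") as fh:
        fh.write("sequence\t" + "\t".join(libraries) + "\n")
        for tag in tags:
            row = "\t".join(str(tag.counts.get(lib, 0)) for lib in libraries)
            fh.write(f"{tag.sequence}\t{row}\n")
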