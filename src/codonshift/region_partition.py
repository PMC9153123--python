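"""Structure labels and region groupings over codon-aligned genes.

Converts raw structure information (DSSP strings, per-residue disorder
scores) into per-codon label tracks, and builds the region groupings whose
codon counts the fitter consumes.  Coordinates are 1-based inclusive codon
indices; codon index equals residue index (initiator ATG is codon 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from codonshift.codon_core import CodonFamilyTable, CodonCountMatrix, count_matrix

__all__ = [
    "UNASSIGNED",
    "GroupingScheme",
    "PartitionResult",
    "dssp_to_three_class",
    "disorder_from_scores",
    "combine_labels",
    "segments_from_labels",
    "build_partitions",
    "enumerate_schemes",
    "split_termini",
    "positions_2_3_split",
    "shift_track",
]

#: label for codons without a structure call; dropped from every group
UNASSIGNED = "unassigned"

_DSSP_MAP = {
    "H": "H", "G": "H", "I": "H",   # helix
    "E": "E", "B": "E",             # sheet
    "S": "C", "T": "C", ".": "C",   # coil (. is the catch-all class)
}


def dssp_to_three_class(
    dssp_string: str, exclude_310_pi: bool = False
) -> list[str]:
    """Collapse a DSSP assignment string to helix/sheet/coil (H/E/C).

    With ``exclude_310_pi`` the 3_10 (G) and pi (I) helix letters are dropped
    to :data:`UNASSIGNED` instead of being counted as helix.
    """
    out = []
    for pos, ch in enumerate(dssp_string, start=1):
        if ch not in _DSSP_MAP:
            raise ValueError(f"unknown DSSP character {ch!r} at position {pos}")
        if exclude_310_pi and ch in ("G", "I"):
            out.append(UNASSIGNED)
        else:
            out.append(_DSSP_MAP[ch])
    return out


def disorder_from_scores(
    scores: Sequence[float], threshold: float = 0.5
) -> list[str]:
    """Threshold per-residue disorder quasi-probabilities.

    Scores strictly greater than the threshold are disordered ("D"); scores
    less than or equal to it are structured ("S").
    """
    out = []
    for pos, s in enumerate(scores, start=1):
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"score {s} at position {pos} outside [0, 1]")
        out.append("D" if s > threshold else "S")
    return out


def combine_labels(
    ss_track: Sequence[str], disorder_track: Sequence[str]
) -> list[str]:
    """Composite labels like ``H^S`` from a secondary-structure and a
    disorder track of equal length; either side's unassigned propagates."""
    if len(ss_track) != len(disorder_track):
        raise ValueError("tracks differ in length")
    out = []
    for ss, dis in zip(ss_track, disorder_track):
        if ss == UNASSIGNED or dis == UNASSIGNED:
            out.append(UNASSIGNED)
        else:
            out.append(f"{ss}^{dis}")
    return out


@dataclass(frozen=True)
class GroupingScheme:
    """A model: a total mapping from structure labels to group names."""

    scheme_id: str
    mapping: Mapping[str, str]

    def group_of(self, label: str) -> str:
        if label not in self.mapping:
            raise KeyError(f"scheme {self.scheme_id}: label {label!r} unmapped")
        return self.mapping[label]

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.mapping.values())))

    @classmethod
    def merged(cls, labels: Iterable[str], scheme_id: str = "null") -> "GroupingScheme":
        return cls(scheme_id, {l: "all" for l in labels})

    @classmethod
    def separate(cls, labels: Iterable[str], scheme_id: str = "separate") -> "GroupingScheme":
        return cls(scheme_id, {l: l for l in labels})


def _partitions_of(items: list[str]):
    # all set partitions (Bell number; alphabet is capped at 6 labels)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions_of(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def enumerate_schemes(labels: Sequence[str]) -> list[GroupingScheme]:
    """Every way of merging the label alphabet into groups.

    Includes the all-merged (null) model, the all-separate model, and every
    intermediate merge; scheme ids are stable strings like ``"E+H|C"``.
    """
    labels = sorted(set(labels))
    if not 2 <= len(labels) <= 6:
        raise ValueError("label alphabet must have 2-6 labels")
    schemes = []
    for part in _partitions_of(labels):
        blocks = sorted("+".join(sorted(b)) for b in part)
        scheme_id = "|".join(blocks)
        mapping = {l: "+".join(sorted(b)) for b in part for l in b}
        schemes.append(GroupingScheme(scheme_id, mapping))
    schemes.sort(key=lambda s: (len(s.groups), s.scheme_id))
    return schemes


@dataclass
class PartitionResult:
    """Per-group codon counts plus the site lists backing them."""

    scheme: GroupingScheme
    group_counts: dict[str, CodonCountMatrix]
    group_sites: dict[str, list[tuple[str, int]]]  # (gene_id, 1-based index)

    def all_sites(self) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for sites in self.group_sites.values():
            out.update(sites)
        return out


def build_partitions(
    sequences: Mapping[str, Sequence[str]],
    label_track: Mapping[str, Sequence[str]],
    scheme: GroupingScheme,
    exclude_first_n: int = 35,
    table: CodonFamilyTable | None = None,
) -> PartitionResult:
    """Assign every labeled codon past the 5'-exclusion to exactly one group.

    The first ``exclude_first_n`` codons of every gene are dropped (weaker
    selection near the 5'-end); unassigned codons are dropped from all groups
    so that every scheme over the same track covers an identical codon set.
    """
    if exclude_first_n < 0:
        raise ValueError("exclude_first_n must be >= 0")
    missing = sorted(set(sequences) - set(label_track))
    if missing:
        raise ValueError(f"genes missing from label track: {missing}")
    table = table or CodonFamilyTable.standard()
    gene_ids = list(sequences)
    group_masks: dict[str, dict[str, list[bool]]] = {g: {} for g in scheme.groups}
    group_sites: dict[str, list[tuple[str, int]]] = {g: [] for g in scheme.groups}
    for gid in gene_ids:
        seq = sequences[gid]
        labels = label_track[gid]
        if len(labels) != len(seq):
            raise ValueError(f"gene {gid}: label track length != sequence length")
        for group in scheme.groups:
            group_masks[group][gid] = [False] * len(seq)
        for i, label in enumerate(labels):
            if i < exclude_first_n or label == UNASSIGNED:
                continue
            group = scheme.group_of(label)
            group_masks[group][gid][i] = True
            group_sites[group].append((gid, i + 1))
    group_counts = {
        group: count_matrix(sequences, masks, table)
        for group, masks in group_masks.items()
    }
    return PartitionResult(scheme, group_counts, group_sites)


def segments_from_labels(
    label_track: Mapping[str, Sequence[str]], label: str | None = None
) -> dict[str, list[tuple[int, int, str]]]:
    """Maximal runs of equal labels as (start, end, label), 1-based inclusive.

    With ``label`` given, only runs of that label are returned.
    """
    segs: dict[str, list[tuple[int, int, str]]] = {}
    for gid, labels in label_track.items():
        out = []
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                if labels[start] != UNASSIGNED and (
                    label is None or labels[start] == label
                ):
                    out.append((start + 1, i, labels[start]))
                start = i
        segs[gid] = out
    return segs


def split_termini(
    segments: Mapping[str, Sequence[tuple[int, int, str]]],
    gene_lengths: Mapping[str, int],
    terminus_size: int = 2,
    min_length: int = 6,
    mode: str = "combined_termini",
) -> dict[str, list[str]]:
    """Label segment codons as termini vs core.

    Segments shorter than ``min_length`` are excluded entirely.  In mode
    ``combined_termini`` the first and last ``terminus_size`` codons share one
    "termini" label; in ``nc_separate`` they are labeled "nterm"/"cterm".  A
    segment long enough to qualify but shorter than twice the terminus size
    has overlapping termini, which is undefined and raises.
    """
    if mode not in ("combined_termini", "nc_separate"):
        raise ValueError(f"unknown mode {mode!r}")
    if terminus_size < 1:
        raise ValueError("terminus_size must be >= 1")
    track = {g: [UNASSIGNED] * n for g, n in gene_lengths.items()}
    for gid, segs in segments.items():
        for start, end, _label in segs:
            length = end - start + 1
            if length < min_length:
                continue
            if length < 2 * terminus_size:
                raise ValueError(
                    f"gene {gid}: segment {start}-{end} of length {length} has "
                    f"overlapping termini at terminus_size={terminus_size}"
                )
            for k in range(terminus_size):
                track[gid][start - 1 + k] = (
                    "termini" if mode == "combined_termini" else "nterm"
                )
                track[gid][end - 1 - k] = (
                    "termini" if mode == "combined_termini" else "cterm"
                )
            for pos in range(start + terminus_size, end - terminus_size + 1):
                track[gid][pos - 1] = "core"
    return track


def positions_2_3_split(
    helix_segments: Mapping[str, Sequence[tuple[int, int, str]]],
    gene_lengths: Mapping[str, int],
    min_length: int = 6,
) -> dict[str, list[str]]:
    """Separate codons 2-3 of each qualifying helix from the remainder.

    Helices shorter than ``min_length`` are excluded; for included helices
    codon 1 and codons 4..L go to "remainder" and codons 2-3 to "pos23".
    """
    track = {g: [UNASSIGNED] * n for g, n in gene_lengths.items()}
    for gid, segs in helix_segments.items():
        for start, end, _label in segs:
            length = end - start + 1
            if length < min_length:
                continue
            for pos in range(start, end + 1):
                offset = pos - start  # 0-based within helix
                track[gid][pos - 1] = "pos23" if offset in (1, 2) else "remainder"
    return track


def shift_track(
    label_track: Mapping[str, Sequence[str]], offset: int
) -> dict[str, list[str]]:
    """Shift labels downstream by ``offset`` codons (cotranslational-folding
    offset); vacated positions become unassigned.  ``offset=0`` is identity."""
    if offset < 0:
        raise ValueError("offset must be >= 0")
    out = {}
    for gid, labels in label_track.items():
        shifted = [UNASSIGNED] * len(labels)
        for i, label in enumerate(labels):
            j = i + offset
            if j < len(labels):
                shifted[j] = label
        out[gid] = shifted
    return out
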