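"""Domain-set containers: flat partitions and two-layer hierarchies.

A :class:`DomainSet` is an ordered list of contiguous, non-overlapping bin
intervals on one chromosome — one layer of TAD-like domains (TLDs).  Bins
not covered by any interval are gap bins.  A :class:`HierarchicalDomains`
nests a sub-domain layer inside a nested-TLD layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DomainSet", "HierarchicalDomains", "labels_from_domains"]


@dataclass
class DomainSet:
    """Ordered contiguous bin intervals (0-based, half-open) on one chromosome."""

    intervals: list  # list of (start_bin, end_bin) half-open
    chrom: str = "chr"
    binsize: int = 1
    n_bins: int | None = None

    def __post_init__(self):
        iv = [(int(a), int(b)) for a, b in self.intervals]
        iv.sort()
        for a, b in iv:
            if b <= a:
                raise ValueError(f"empty or inverted interval ({a}, {b})")
        for (a1, b1), (a2, b2) in zip(iv, iv[1:]):
            if a2 < b1:
                raise ValueError(f"overlapping intervals ({a1},{b1}) and ({a2},{b2})")
        self.intervals = iv

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other):
        return (
            isinstance(other, DomainSet)
            and self.intervals == other.intervals
            and self.chrom == other.chrom
        )

    @property
    def sizes(self) -> np.ndarray:
        return np.array([b - a for a, b in self.intervals], dtype=int)

    @property
    def span(self) -> int:
        """Smallest n_bins consistent with the intervals (or the declared one)."""
        if self.n_bins is not None:
            return self.n_bins
        return max((b for _, b in self.intervals), default=0)

    def boundaries_bp(self) -> list:
        """Shared bp coordinates of edges between consecutive adjacent domains."""
        out = []
        for (a1, b1), (a2, b2) in zip(self.intervals, self.intervals[1:]):
            if b1 == a2:
                out.append(b1 * self.binsize)
        return out

    def covered_bins(self) -> np.ndarray:
        n = self.span
        mask = np.zeros(n, dtype=bool)
        for a, b in self.intervals:
            mask[a:b] = True
        return mask

    def to_bed(self, path, level=None) -> None:
        with open(path, "w") as fh:
            for a, b in self.intervals:
                row = f"{self.chrom}\t{a * self.binsize}\t{b * self.binsize}"
                if level is not None:
                    row += f"\t{level}"
                fh.write(row + "\n")

    @classmethod
    def from_bed(cls, path, binsize, chrom=None, n_bins=None) -> "DomainSet":
        iv, got_chrom = [], chrom
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                c, s, e = parts[0], int(parts[1]), int(parts[2])
                if chrom is not None and c != chrom:
                    continue
                got_chrom = got_chrom or c
                iv.append((s // binsize, -(-e // binsize)))
        return cls(iv, chrom=got_chrom or "chr", binsize=binsize, n_bins=n_bins)


@dataclass
class HierarchicalDomains:
    """Two-layer nesting: nested TLDs, each tiled by subTLDs.

    ``parents[k]`` gives the index of the nested TLD containing subTLD ``k``.
    """

    nested: DomainSet
    sub: DomainSet
    parents: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.parents) != len(self.sub):
            raise ValueError("parents must map every subTLD to a nested TLD")
        for k, p in enumerate(self.parents):
            (na, nb) = self.nested[p]
            (sa, sb) = self.sub[k]
            if sa < na or sb > nb:
                raise ValueError(
                    f"subTLD ({sa},{sb}) not contained in nested TLD ({na},{nb})"
                )

    def children(self, parent_idx) -> list:
        return [self.sub[k] for k, p in enumerate(self.parents) if p == parent_idx]


def labels_from_domains(ds: DomainSet, n_bins=None, label_gaps=True) -> np.ndarray:
    """Per-bin integer community labels from a domain set.

    Each domain gets its own label; contiguous gap stretches get their own
    labels too when ``label_gaps`` (the convention for AMI, where predicted
    domains and the intermediate windows between them both count).  With
    ``label_gaps=False`` gap bins are labelled -1.
    """
    n = n_bins if n_bins is not None else ds.span
    labels = np.full(n, -1, dtype=int)
    nxt = 0
    for a, b in ds.intervals:
        labels[a:b] = nxt
        nxt += 1
    if label_gaps:
        in_gap = False
        for i in range(n):
            if labels[i] == -1:
                if not in_gap:
                    cur = nxt
                    nxt += 1
                    in_gap = True
                labels[i] = cur
            else:
                in_gap = False
    return labels
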