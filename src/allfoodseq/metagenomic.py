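"""Taxonomic binning of residual unmapped reads.

Reads that never map to the panel are searched against a sequence database
externally (BLASTN or similar); this module consumes the 12-column tabular
output (outfmt 6 / m8), filters the hits, and assigns each read to the lowest
common ancestor (LCA) of its surviving hits in an NCBI-style taxonomy.
Filters mirror the MEGAN-style parameter set used for this application:
a minimum bitscore, retention of hits within a small percentage of the
read's best bitscore, a read-complexity floor that discards low-complexity
(microsatellite-like) reads, and a minimum per-taxon read support below which
a taxon is folded into its ancestors. Taxa attracting many reads are flagged
for promotion into the mapping panel so quantification can be repeated with
their genome included.

The complexity measure here is the Shannon entropy of overlapping
trinucleotide frequencies normalized by ``log2(min(64, L - 2))`` — a stated
stand-in, since the original tool's internal measure is unpublished.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthgen import M8_COLUMNS

log = logging.getLogger(__name__)

__all__ = [
    "Taxonomy",
    "LcaParams",
    "TaxonSummary",
    "parse_m8",
    "read_complexity",
    "assign_reads",
    "summarize",
]


class Taxonomy:
    """Rooted taxonomy: id -> (parent id, rank, name).

    Accepts the NCBI ``nodes.dmp``/``names.dmp`` dialect or a simple
    4-column TSV (id, parent id, rank, name). The root is its own parent.
    """

    def __init__(self, nodes: Mapping[int, tuple[int, str, str]]):
        self.parent: dict[int, int] = {}
        self.rank: dict[int, str] = {}
        self.name: dict[int, str] = {}
        roots = []
        for tid, (pid, rank, name) in nodes.items():
            self.parent[tid] = pid
            self.rank[tid] = rank
            self.name[tid] = name
            if pid == tid:
                roots.append(tid)
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots[0]
        for tid in self.parent:
            if self.parent[tid] not in self.parent:
                raise ValueError(f"parent of taxon {tid} is not in the taxonomy")
        self._depth: dict[int, int] = {}
        for tid in self.parent:
            self.depth(tid)  # also detects cycles

    def depth(self, tid: int) -> int:
        chain = []
        t = tid
        while t not in self._depth and t != self.root:
            chain.append(t)
            t = self.parent[t]
            if len(chain) > len(self.parent):
                raise ValueError(f"cycle in taxonomy at taxon {tid}")
        base = 0 if t == self.root else self._depth[t]
        for i, u in enumerate(reversed(chain), start=1):
            self._depth[u] = base + i
        self._depth.setdefault(self.root, 0)
        return self._depth[tid]

    def __contains__(self, tid: int) -> bool:
        return tid in self.parent

    def lineage(self, tid: int) -> list[int]:
        """Path from ``tid`` up to and including the root."""
        out = [tid]
        while out[-1] != self.root:
            out.append(self.parent[out[-1]])
        return out

    def lca(self, taxa: Iterable[int]) -> int:
        """Lowest common ancestor of a set of taxa (idempotent, commutative)."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca of an empty set")
        cur = taxa[0]
        for t in taxa[1:]:
            a, b = cur, t
            da, db = self.depth(a), self.depth(b)
            while da > db:
                a, da = self.parent[a], da - 1
            while db > da:
                b, db = self.parent[b], db - 1
            while a != b:
                a, b = self.parent[a], self.parent[b]
            cur = a
            if cur == self.root:
                break
        return cur

    def children(self) -> dict[int, list[int]]:
        kids: dict[int, list[int]] = {t: [] for t in self.parent}
        for t, p in self.parent.items():
            if t != p:
                kids[p].append(t)
        return kids

    def leaves(self) -> list[int]:
        kids = self.children()
        return [t for t, c in kids.items() if not c]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Taxonomy":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["id", "parent", "rank", "name"]
        )
        return cls(
            {
                int(r.id): (int(r.parent), str(r.rank), str(r.name))
                for r in df.itertuples()
            }
        )

    @classmethod
    def from_ncbi_dmp(cls, nodes_path: str | Path, names_path: str | Path) -> "Taxonomy":
        nodes: dict[int, tuple[int, str, str]] = {}
        with open(nodes_path) as fh:
            for line in fh:
                parts = [p.strip() for p in line.rstrip("\t|\n").split("\t|\t")]
                tid, pid, rank = int(parts[0]), int(parts[1]), parts[2]
                nodes[tid] = (pid, rank, "")
        names: dict[int, str] = {}
        with open(names_path) as fh:
            for line in fh:
                parts = [p.strip() for p in line.rstrip("\t|\n").split("\t|\t")]
                if len(parts) >= 4 and parts[3] == "scientific name":
                    names[int(parts[0])] = parts[1]
        return cls(
            {tid: (pid, rank, names.get(tid, "")) for tid, (pid, rank, _) in nodes.items()}
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        rows = [
            (t, self.parent[t], self.rank[t], self.name[t]) for t in sorted(self.parent)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
        return path


@dataclass(frozen=True)
class LcaParams:
    """Filter thresholds for the LCA stage.

    min_score: hits below this bitscore are discarded (default 75.0).
    top_percent: retain hits with bitscore >= (1 - top_percent/100) * best
        surviving hit of the read (default 1.0).
    min_complexity: reads below this trinucleotide-entropy score are set
        aside as low-complexity (default 0.44).
    max_hits_per_read: best hits kept per read (default 3).
    min_support: a taxon needs strictly more than this many reads to be
        reported on its own; otherwise it is folded into its ancestors
        (default 50).
    promote_threshold: taxa with more reads than this are recommended for
        inclusion in the mapping panel (default 1000).
    """

    min_score: float = 75.0
    top_percent: float = 1.0
    min_complexity: float = 0.44
    max_hits_per_read: int = 3
    min_support: int = 50
    promote_threshold: int = 1000

    def __post_init__(self) -> None:
        for name in ("min_score", "top_percent", "min_complexity", "min_support",
                     "promote_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.top_percent > 100:
            raise ValueError("top_percent must be <= 100")
        if self.max_hits_per_read < 1:
            raise ValueError("max_hits_per_read must be >= 1")


def parse_m8(
    path_or_df: str | Path | pd.DataFrame,
    subject_taxon_map: Mapping[str, int] | str | Path,
    max_hits_per_read: int = 3,
) -> pd.DataFrame:
    """Parse 12-column tabular similarity output into per-read top hits.

    Hits are annotated with ``taxon_id`` via the subject->taxon map (subjects
    absent from the map are logged and dropped), sorted per read by
    descending bitscore and truncated to ``max_hits_per_read``; ties at the
    cutoff keep the lexicographically smallest subject id.
    """
    if isinstance(subject_taxon_map, (str, Path)):
        m = pd.read_csv(subject_taxon_map, sep="\t", header=None,
                        names=["subject", "taxon"])
        subject_taxon_map = dict(zip(m["subject"].astype(str), m["taxon"].astype(int)))
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
        if list(df.columns) != M8_COLUMNS:
            raise ValueError("hit frame must carry the 12 standard columns")
    else:
        try:
            df = pd.read_csv(
                path_or_df, sep="\t", header=None, names=M8_COLUMNS,
                dtype={"qseqid": str, "sseqid": str},
            )
        except Exception as e:
            raise ValueError(f"{path_or_df}: malformed tabular hit file: {e}") from e
        if len(df):
            numeric = df[["pident", "bitscore", "length", "mismatch"]].apply(
                pd.to_numeric, errors="coerce"
            )
            bad_rows = numeric.isna().any(axis=1)
            if bad_rows.any():
                raise ValueError(
                    f"{path_or_df}: malformed record at line {int(bad_rows.idxmax()) + 1}"
                )
            df[numeric.columns] = numeric
    if df.empty:
        df["taxon_id"] = pd.Series(dtype=np.int64)
        return df
    taxon = df["sseqid"].map(subject_taxon_map)
    unknown = taxon.isna()
    if unknown.any():
        log.warning(
            "dropping %d hits to subjects without taxon mapping (e.g. %s)",
            int(unknown.sum()), df.loc[unknown, "sseqid"].iloc[0],
        )
        df = df[~unknown]
        taxon = taxon[~unknown]
    df = df.assign(taxon_id=taxon.astype(np.int64))
    df = df.sort_values(
        ["qseqid", "bitscore", "sseqid"], ascending=[True, False, True],
        kind="stable",
    )
    return df.groupby("qseqid", sort=False).head(max_hits_per_read).reset_index(drop=True)


def read_complexity(sequence: str) -> float:
    """Normalized trinucleotide Shannon entropy of a read, in [0, 1].

    Entropy of overlapping 3-mer frequencies divided by
    ``log2(min(64, L - 2))``; a homopolymer scores 0, uniform-random 100-mers
    score close to 1.
    """
    L = len(sequence)
    if L < 3:
        raise ValueError("complexity needs a sequence of length >= 3")
    counts = Counter(sequence[i : i + 3] for i in range(L - 2))
    n = L - 2
    h = -sum((c / n) * math.log2(c / n) for c in counts.values())
    return h / math.log2(min(64, n)) if n > 1 else 0.0


def assign_reads(
    hits: pd.DataFrame,
    reads: Mapping[str, str],
    taxonomy: Taxonomy,
    params: LcaParams = LcaParams(),
) -> pd.DataFrame:
    """Assign each read to the LCA of its filtered hits.

    ``hits`` is the frame from :func:`parse_m8`; ``reads`` maps read id to
    sequence (the universe of reads — reads without hits are classified
    ``unassigned``). Order of filters: read complexity, min_score,
    top_percent relative to the read's best surviving hit, then LCA. Hits to
    taxa absent from the taxonomy are unusable and logged.

    Returns a frame indexed by read id with columns ``category`` (assigned /
    unassigned / low_complexity) and ``taxon_id`` (-1 when not assigned).
    """
    known = hits["taxon_id"].isin(list(taxonomy.parent))
    if (~known).any():
        log.warning(
            "ignoring %d hits to taxa absent from the taxonomy", int((~known).sum())
        )
        hits = hits[known]
    by_read: dict[str, pd.DataFrame] = dict(tuple(hits.groupby("qseqid", sort=False)))
    rows = []
    for rid, seq in reads.items():
        if read_complexity(seq) < params.min_complexity:
            rows.append((rid, "low_complexity", -1))
            continue
        sub = by_read.get(rid)
        if sub is None:
            rows.append((rid, "unassigned", -1))
            continue
        scores = sub["bitscore"].to_numpy()
        keep = scores >= params.min_score
        if not keep.any():
            rows.append((rid, "unassigned", -1))
            continue
        best = scores[keep].max()
        keep &= scores >= (1.0 - params.top_percent / 100.0) * best
        taxa = sub.loc[keep, "taxon_id"].unique()
        rows.append((rid, "assigned", int(taxonomy.lca(taxa))))
    out = pd.DataFrame(rows, columns=["read_id", "category", "taxon_id"])
    return out.set_index("read_id")


@dataclass
class TaxonSummary:
    """Per-taxon read counts after support folding, plus bookkeeping.

    ``counts`` is indexed by taxon id; ``promotions`` lists (taxon id, name,
    count) for taxa recommended for the mapping panel; ``unassigned`` and
    ``low_complexity`` are the two classes of unassignable reads.
    """

    counts: pd.Series
    names: pd.Series
    promotions: list[tuple[int, str, int]]
    unassigned: int
    low_complexity: int

    @property
    def assigned(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"taxon_id": self.counts.index, "name": self.names.values,
             "reads": self.counts.values}
        ).set_index("taxon_id")


def summarize(
    assignments: pd.DataFrame,
    taxonomy: Taxonomy,
    params: LcaParams = LcaParams(),
    fold_unsupported: bool = True,
) -> TaxonSummary:
    """Aggregate per-read assignments into a supported-taxon summary.

    Taxa with at most ``min_support`` reads ("more than" is strict) are folded
    into their parents, children before parents, until a supported ancestor
    or the root absorbs them; with ``fold_unsupported=False`` they are
    discarded instead. Taxa whose final count exceeds ``promote_threshold``
    (root excluded) are flagged for promotion into the mapping panel.
    """
    assigned = assignments[assignments["category"] == "assigned"]
    counts = Counter(int(t) for t in assigned["taxon_id"])
    for tid in sorted(counts, key=taxonomy.depth, reverse=True):
        c = counts[tid]
        if tid != taxonomy.root and c <= params.min_support:
            del counts[tid]
            if fold_unsupported:
                counts[taxonomy.parent[tid]] += c
    series = pd.Series(dict(counts), dtype=np.int64).sort_values(ascending=False)
    names = pd.Series({t: taxonomy.name[t] for t in series.index})
    promotions = [
        (int(t), taxonomy.name[int(t)], int(c))
        for t, c in series.items()
        if c > params.promote_threshold and t != taxonomy.root
    ]
    return TaxonSummary(
        counts=series,
        names=names,
        promotions=promotions,
        unassigned=int((assignments["category"] == "unassigned").sum()),
        low_complexity=int((assignments["category"] == "low_complexity").sum()),
    )
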