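"""Synthetic reference panels and simulated sequencing reads.

This module generates the validation inputs for the read-counting
quantification pipeline: panels of reference genomes derived from shared
ancestral sequences at controlled per-site divergence, optionally degraded
with N-masked blocks to emulate draft-assembly incompleteness, and mixtures
of origin-tagged reads with a flat per-base substitution error model. It also
fabricates 12-column similarity-search (BLAST outfmt-6 / m8) hit tables so
the taxonomic-binning stage can be exercised without a sequence database.

All randomness flows through :class:`numpy.random.Generator` objects seeded
from the integer seeds carried by the specs, so identical specs produce
byte-identical FASTA/FASTQ output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codec import REF_N, decode, encode_read, encode_ref, revcomp

log = logging.getLogger(__name__)

__all__ = [
    "GenomeSpec",
    "Genome",
    "GenomePanel",
    "MixtureSpec",
    "TaggedReadSet",
    "generate_panel",
    "apply_n_mask",
    "largest_remainder",
    "simulate_reads",
    "make_m8_fixture",
    "write_m8",
]

M8_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Recipe for one synthetic reference genome.

    Parameters
    ----------
    name : species label, unique within a panel.
    length : genome length in bases.
    gc : target GC fraction of the ancestral sequence.
    divergence : per-site substitution probability applied against the shared
        ancestor, in [0, 0.5]. Two genomes mutated independently at rate *d*
        from the same ancestor differ at an expected fraction
        ``1 - ((1-d)**2 + d**2/3)`` of sites.
    n_fraction : fraction of positions replaced by contiguous N runs, in
        [0, 1); emulates draft-genome incompleteness.
    ancestor : group label; specs sharing a label are mutated copies of one
        ancestral sequence and therefore correlated.
    seed : per-genome seed for the mutation/masking random stream.
    """

    name: str
    length: int
    gc: float = 0.42
    divergence: float = 0.0
    n_fraction: float = 0.0
    ancestor: str = "shared"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"genome length must be positive, got {self.length}")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"gc must be in [0, 1], got {self.gc}")
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError(f"divergence must be in [0, 0.5], got {self.divergence}")
        if not 0.0 <= self.n_fraction < 1.0:
            raise ValueError(f"n_fraction must be in [0, 1), got {self.n_fraction}")


@dataclass
class Genome:
    """A named reference sequence held as an encoded uint8 array."""

    name: str
    codes: np.ndarray

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def n_count(self) -> int:
        """Number of ambiguous (N) positions."""
        return int(np.count_nonzero(self.codes >= REF_N))

    @property
    def seq(self) -> str:
        return decode(self.codes)

    @classmethod
    def from_seq(cls, name: str, seq: str) -> "Genome":
        return cls(name, encode_ref(seq))


class GenomePanel:
    """Ordered collection of reference genomes a sample is quantified against."""

    def __init__(self, genomes: Iterable[Genome] = ()):
        self._genomes: dict[str, Genome] = {}
        for g in genomes:
            self.add(g)

    def add(self, genome: Genome) -> None:
        if genome.name in self._genomes:
            raise ValueError(f"duplicate genome name: {genome.name!r}")
        self._genomes[genome.name] = genome

    @property
    def names(self) -> list[str]:
        return list(self._genomes)

    def __len__(self) -> int:
        return len(self._genomes)

    def __iter__(self):
        return iter(self._genomes.values())

    def __contains__(self, name: str) -> bool:
        return name in self._genomes

    def __getitem__(self, name: str) -> Genome:
        return self._genomes[name]

    def subset(self, names: Sequence[str]) -> "GenomePanel":
        return GenomePanel(self._genomes[n] for n in names)

    def quality(self) -> pd.DataFrame:
        """Per-genome quality table: total length ``c``, ambiguous count ``n``
        and the completeness correction factor ``f = (n + c) / c``."""
        rows = []
        for g in self:
            c, n = len(g), g.n_count
            rows.append((g.name, c, n, (n + c) / c))
        return pd.DataFrame(rows, columns=["genome", "c", "n", "f"]).set_index("genome")

    def to_fasta(self, path: str | Path, wrap: int = 70) -> Path:
        path = Path(path)
        records = (SeqRecord(Seq(g.seq), id=g.name, description="") for g in self)
        with open(path, "w") as handle:
            writer = SeqIO.FastaIO.FastaWriter(handle, wrap=wrap)
            writer.write_file(records)
        return path

    @classmethod
    def from_fasta(cls, paths: str | Path | Sequence[str | Path]) -> "GenomePanel":
        if isinstance(paths, (str, Path)):
            paths = [paths]
        panel = cls()
        for p in paths:
            for rec in SeqIO.parse(str(p), "fasta"):
                panel.add(Genome.from_seq(rec.id, str(rec.seq)))
        return panel


def _random_codes(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform substitutions: each site flips to one of the 3 other bases."""
    out = codes.copy()
    if rate <= 0:
        return out
    hit = rng.random(out.size) < rate
    k = int(hit.sum())
    out[hit] = (out[hit] + rng.integers(1, 4, size=k, dtype=np.uint8)) % 4
    return out


def apply_n_mask(
    codes: np.ndarray,
    n_fraction: float,
    rng: np.random.Generator,
    mean_block: int = 1000,
) -> np.ndarray:
    """Replace ~``n_fraction`` of positions with contiguous N blocks.

    Blocks have geometric lengths (mean ``mean_block``); the final block is
    trimmed so the realized N count equals ``round(n_fraction * len)`` exactly.
    """
    out = codes.copy()
    target = int(round(n_fraction * out.size))
    if target <= 0:
        return out
    if target >= out.size:
        raise ValueError("n_fraction leaves no unmasked sequence")
    current = int(np.count_nonzero(out >= REF_N))
    while current < target:
        blk = min(int(rng.geometric(1.0 / mean_block)), target - current)
        start = int(rng.integers(0, out.size - blk + 1))
        window = out[start : start + blk]
        added = int(np.count_nonzero(window < REF_N))
        window[:] = REF_N
        current += added
    return out


def generate_panel(
    specs: Sequence[GenomeSpec], shared_ancestor_seed: int = 0
) -> GenomePanel:
    """Build a panel of genomes from specs.

    One ancestral sequence is generated per distinct ``ancestor`` label (its
    length is the maximum over the group, its GC that of the group's first
    spec); each genome is an independently mutated, optionally N-masked copy.
    Deterministic under fixed seeds.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("genome names must be unique")
    groups: dict[str, list[GenomeSpec]] = {}
    for s in specs:
        groups.setdefault(s.ancestor, []).append(s)

    panel = GenomePanel()
    for gi, (label, members) in enumerate(groups.items()):
        anc_len = max(m.length for m in members)
        anc_rng = np.random.default_rng([shared_ancestor_seed, gi])
        ancestor = _random_codes(anc_len, members[0].gc, anc_rng)
        for spec in members:
            rng = np.random.default_rng([shared_ancestor_seed, gi, spec.seed])
            codes = _mutate(ancestor[: spec.length], spec.divergence, rng)
            if spec.n_fraction > 0:
                codes = apply_n_mask(codes, spec.n_fraction, rng)
            panel.add(Genome(spec.name, codes))
    return panel


@dataclass(frozen=True)
class MixtureSpec:
    """Composition and sequencing parameters for a simulated read mixture.

    ``components`` maps species labels to proportions in percent (must sum to
    100). With ``exact_counts`` the per-species read counts are the
    largest-remainder allocation of ``round(p/100 * total_reads)``; otherwise
    they are drawn from a multinomial.
    """

    components: Mapping[str, float]
    total_reads: int
    read_length: int = 100
    error_rate: float = 0.01
    paired: bool = False
    insert_mean: float = 300.0
    insert_sd: float = 50.0
    exact_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.components.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"proportions must sum to 100, got {total}")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")


def largest_remainder(proportions: Sequence[float], total: int) -> np.ndarray:
    """Allocate ``total`` items to proportions (in percent), summing exactly.

    Each component receives ``floor(p/100 * total)``; leftover items go to the
    components with the largest fractional remainders (ties broken by order).
    """
    exact = np.asarray(proportions, dtype=float) / 100.0 * total
    base = np.floor(exact).astype(np.int64)
    leftover = int(total - base.sum())
    if leftover:
        order = np.argsort(-(exact - base), kind="stable")
        base[order[:leftover]] += 1
    return base


@dataclass
class TaggedReadSet:
    """Simulated reads with ground-truth origin labels.

    ``codes`` is an (n_reads, read_length) uint8 matrix; read ids encode the
    origin species and source coordinates (``species|serial|position|strand``)
    and the same truth is available as arrays / a sidecar TSV.
    """

    ids: np.ndarray
    codes: np.ndarray
    origins: np.ndarray | None = None
    positions: np.ndarray | None = None
    strands: np.ndarray | None = None
    mates: np.ndarray | None = None

    def __len__(self) -> int:
        return int(self.codes.shape[0])

    @property
    def read_length(self) -> int:
        return int(self.codes.shape[1])

    def sequences(self) -> list[str]:
        return [decode(row) for row in self.codes]

    def truth_frame(self) -> pd.DataFrame:
        if self.origins is None:
            raise ValueError("read set carries no ground-truth tags")
        return pd.DataFrame(
            {
                "read_id": self.ids,
                "origin": self.origins,
                "genome": self.origins,
                "position": self.positions,
                "strand": self.strands,
            }
        )

    def to_truth_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.truth_frame().to_csv(path, sep="\t", index=False)
        return path

    def to_fastq(self, path: str | Path) -> Path:
        """Write reads as FASTQ with constant top quality ('I', Phred 40)."""
        path = Path(path)
        qual = "I" * self.read_length
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.codes):
                fh.write(f"@{rid}\n{decode(row)}\n+\n{qual}\n")
        return path

    @classmethod
    def from_fastq(cls, path: str | Path) -> "TaggedReadSet":
        """Load a uniform-length FASTQ (no truth tags)."""
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fastq"):
            ids.append(rec.id)
            rows.append(encode_read(str(rec.seq)))
        lengths = {r.size for r in rows}
        if len(lengths) > 1:
            raise ValueError(
                "reads have heterogeneous lengths; length-filter them first"
            )
        codes = np.vstack(rows) if rows else np.empty((0, 0), dtype=np.uint8)
        return cls(np.array(ids, dtype=object), codes)

    def select(self, idx: np.ndarray) -> "TaggedReadSet":
        take = lambda a: None if a is None else a[idx]
        return TaggedReadSet(
            self.ids[idx],
            self.codes[idx],
            take(self.origins),
            take(self.positions),
            take(self.strands),
            take(self.mates),
        )

    def subsample(self, size: int, rng: np.random.Generator) -> "TaggedReadSet":
        if size > len(self):
            raise ValueError(f"subsample size {size} exceeds pool of {len(self)}")
        idx = rng.choice(len(self), size=size, replace=False)
        return self.select(idx)


def _valid_starts(codes: np.ndarray, window: int) -> np.ndarray:
    """Start positions whose ``window``-length slice is free of N."""
    n = codes.size
    if n < window:
        return np.empty(0, dtype=np.int64)
    bad = (codes >= REF_N).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    win_bad = cs[window:] - cs[:-window]
    return np.flatnonzero(win_bad == 0)


def _apply_errors(
    reads: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    if error_rate <= 0:
        return reads
    hit = rng.random(reads.shape) < error_rate
    k = int(hit.sum())
    reads[hit] = (reads[hit] + rng.integers(1, 4, size=k, dtype=np.uint8)) % 4
    return reads


def simulate_reads(panel: GenomePanel, mix: MixtureSpec) -> TaggedReadSet:
    """Simulate a tagged read mixture from a genome panel.

    Reads are drawn uniformly at random from N-free windows on either strand;
    each base substitutes to a different base with probability
    ``mix.error_rate``. Ground truth (origin species, 0-based source position
    of the forward-strand window, strand) is kept in the ids and arrays.
    """
    rng = np.random.default_rng(mix.seed)
    L = mix.read_length
    names = list(mix.components)
    for name in names:
        if name not in panel:
            raise ValueError(f"mixture component {name!r} not in panel")
        if len(panel[name]) < L:
            raise ValueError(f"genome {name!r} shorter than read length {L}")

    props = [mix.components[n] for n in names]
    if mix.exact_counts:
        counts = largest_remainder(props, mix.total_reads)
    else:
        counts = rng.multinomial(mix.total_reads, np.asarray(props) / 100.0)

    if mix.paired:
        return _simulate_paired(panel, mix, names, counts, rng)

    all_ids, all_codes, all_orig, all_pos, all_strand = [], [], [], [], []
    serial = 0
    for name, n_reads in zip(names, counts):
        if n_reads == 0:
            continue
        g = panel[name]
        starts = _valid_starts(g.codes, L)
        if starts.size == 0:
            raise ValueError(f"genome {name!r} has no N-free window of length {L}")
        pos = starts[rng.integers(0, starts.size, size=n_reads)]
        strand = rng.integers(0, 2, size=n_reads).astype(np.int8)
        windows = g.codes[pos[:, None] + np.arange(L)]
        rev = strand == 1
        windows[rev] = revcomp(windows[rev])
        reads = _apply_errors(windows, mix.error_rate, rng)
        ids = np.array(
            [
                f"{name}|{serial + i}|{p}|{'-' if s else '+'}"
                for i, (p, s) in enumerate(zip(pos, strand))
            ],
            dtype=object,
        )
        serial += int(n_reads)
        all_ids.append(ids)
        all_codes.append(reads)
        all_orig.append(np.full(n_reads, name, dtype=object))
        all_pos.append(pos)
        all_strand.append(strand)

    ids = np.concatenate(all_ids)
    codes = np.vstack(all_codes)
    orig = np.concatenate(all_orig)
    pos = np.concatenate(all_pos)
    strand = np.concatenate(all_strand)
    # shuffle so read order carries no composition signal
    perm = rng.permutation(ids.size)
    return TaggedReadSet(ids[perm], codes[perm], orig[perm], pos[perm], strand[perm])


def _simulate_paired(panel, mix, names, counts, rng):
    """Paired-end fragments: insert length from a truncated normal
    (min = read_length); mate 1 forward, mate 2 reverse-complement."""
    L = mix.read_length
    ids, codes, orig, pos_l, strand_l, mates = [], [], [], [], [], []
    serial = 0
    for name, n_pairs in zip(names, (counts + 1) // 2):
        if n_pairs == 0:
            continue
        g = panel[name]
        made = 0
        guard = 0
        while made < n_pairs:
            guard += 1
            if guard > 1000:
                raise ValueError(f"cannot place paired fragments on {name!r}")
            want = n_pairs - made
            insert = np.maximum(
                np.rint(rng.normal(mix.insert_mean, mix.insert_sd, size=want)), L
            ).astype(np.int64)
            starts = _valid_starts(g.codes, L)
            p1 = starts[rng.integers(0, starts.size, size=want)]
            p2 = p1 + insert - L
            ok = p2 + L <= len(g)
            # mate window must itself be N-free
            bad = (g.codes >= REF_N).astype(np.int64)
            cs = np.concatenate(([0], np.cumsum(bad)))
            ok &= (cs[np.minimum(p2 + L, len(g))] - cs[np.minimum(p2, len(g))]) == 0
            p1, p2 = p1[ok], p2[ok]
            for a, b in ((p1, 0), (p2, 1)):
                w = g.codes[a[:, None] + np.arange(L)]
                if b == 1:
                    w = revcomp(w)
                w = _apply_errors(w.copy(), mix.error_rate, rng)
                tag = "+" if b == 0 else "-"
                rid = np.array(
                    [f"{name}|{serial + i}|{p}|{tag}/{b + 1}" for i, p in enumerate(a)],
                    dtype=object,
                )
                mate = np.array(
                    [
                        f"{name}|{serial + i}|{q}|{'-' if b == 0 else '+'}/{2 - b}"
                        for i, q in enumerate(p2 if b == 0 else p1)
                    ],
                    dtype=object,
                )
                ids.append(rid)
                codes.append(w)
                orig.append(np.full(a.size, name, dtype=object))
                pos_l.append(a)
                strand_l.append(np.full(a.size, b, dtype=np.int8))
                mates.append(mate)
            serial += int(p1.size)
            made += int(p1.size)
    return TaggedReadSet(
        np.concatenate(ids),
        np.vstack(codes),
        np.concatenate(orig),
        np.concatenate(pos_l),
        np.concatenate(strand_l),
        np.concatenate(mates),
    )


def make_m8_fixture(
    reads: TaggedReadSet,
    taxonomy,
    origin_taxids: Mapping[str, int],
    n_confounders: int = 0,
    confounder_frac: float = 0.9,
    best_bitscore: float = 200.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Fabricate a 12-column tabular hit file for a tagged read set.

    Each read receives one hit to its true taxon at ``best_bitscore`` plus
    ``n_confounders`` hits to random other leaf taxa at
    ``confounder_frac * best_bitscore``. Returns the hit table and the
    subject-id -> taxon-id map. Deterministic under ``seed``.
    """
    if reads.origins is None:
        raise ValueError("m8 fixture needs ground-truth origin tags")
    missing = set(reads.origins) - set(origin_taxids)
    if missing:
        raise ValueError(f"origin labels without taxon mapping: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    leaves = sorted(taxonomy.leaves())
    L = reads.read_length
    rows = []
    subject_map: dict[str, int] = {}

    def subject(tid: int) -> str:
        sid = f"subj{tid}"
        subject_map[sid] = tid
        return sid

    for rid, origin in zip(reads.ids, reads.origins):
        true_tid = origin_taxids[origin]
        rows.append(
            (rid, subject(true_tid), 100.0, L, 0, 0, 1, L, 1, L, 1e-50, best_bitscore)
        )
        others = [t for t in leaves if t != true_tid]
        for _ in range(n_confounders):
            tid = others[int(rng.integers(0, len(others)))] if others else true_tid
            rows.append(
                (
                    rid,
                    subject(tid),
                    95.0,
                    L,
                    int(round(L * 0.05)),
                    0,
                    1,
                    L,
                    1,
                    L,
                    1e-20,
                    round(confounder_frac * best_bitscore, 1),
                )
            )
    return pd.DataFrame(rows, columns=M8_COLUMNS), subject_map


def write_m8(hits: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    hits.to_csv(path, sep="\t", header=False, index=False)
    return path
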