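"""Exact k-mismatch read mapping against a multi-genome panel.

A self-contained stand-in for an external short-read aligner, restricted to
ungapped (Hamming-distance) alignment. Correctness rests on the pigeonhole
principle: a read split into ``k+1`` non-overlapping blocks can carry at most
``k`` mismatches, so at least one block — and hence the fixed-length seed at
its start — matches the reference exactly. Looking up all ``k+1`` seeds on
both strands therefore enumerates *every* alignment within the mismatch
allowance; candidates are verified by direct comparison, so no alignment with
more than ``k`` mismatches is ever reported.

The index stores every N-free seed of every genome as a 2-bit packed integer
in a sorted array; queries are vectorized ``searchsorted`` lookups, which
keeps mapping a million 100 bp reads against several megabases of reference
within interactive time on one core.

Ambiguous reference positions (N) count as a mismatch against any read base.
External aligners can substitute for this module via :func:`read_sam`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from ._codec import REF_N, decode, encode_read, revcomp
from .synthgen import GenomePanel

log = logging.getLogger(__name__)

__all__ = ["Alignment", "SeedIndex", "build_index", "map_read", "read_sam", "write_sam"]

_VERIFY_CHUNK = 2_000_000  # candidate windows verified per batch (memory bound)


@dataclass(frozen=True)
class Alignment:
    """One ungapped alignment of a read to a panel genome.

    ``position`` is the 0-based leftmost coordinate on the forward strand of
    the genome; for strand ``'-'`` the reverse complement of the read matches
    the forward reference starting there.
    """

    read_id: str
    genome: str
    position: int
    strand: str
    mismatches: int


class SeedIndex:
    """Sorted-array index of all N-free fixed-length seeds of a panel."""

    def __init__(self, panel: GenomePanel, seed_length: int = 20,
                 read_length: int = 100, k_max: int = 3):
        if seed_length < 4:
            raise ValueError("seed_length must be >= 4")
        if seed_length < 10:
            log.warning(
                "seed_length %d below 10: expect many spurious seed hits on "
                "realistic genomes", seed_length,
            )
        if seed_length > read_length // (k_max + 1):
            raise ValueError(
                f"seed_length {seed_length} too large for k_max={k_max} at "
                f"read length {read_length}: pigeonhole completeness would break"
            )
        if len(panel) == 0:
            raise ValueError("empty panel")
        if len(panel) > 62:
            raise ValueError("panels above 62 genomes are not supported")
        self.seed_length = seed_length
        self.names: list[str] = panel.names
        self.lengths = np.array([len(panel[n]) for n in self.names], dtype=np.int64)
        self.offsets = np.concatenate(([0], np.cumsum(self.lengths)))
        self.codes = np.concatenate([panel[n].codes for n in self.names])

        hashes, positions = [], []
        for gi, name in enumerate(self.names):
            h, p = self._genome_seeds(panel[name].codes, seed_length)
            hashes.append(h)
            positions.append(p + self.offsets[gi])
        h = np.concatenate(hashes) if hashes else np.empty(0, np.int64)
        p = np.concatenate(positions) if positions else np.empty(0, np.int64)
        order = np.argsort(h, kind="stable")
        self.sorted_hash = h[order]
        self.sorted_pos = p[order]

    @staticmethod
    def _genome_seeds(codes: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
        n = codes.size
        if n < L:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        c = codes.astype(np.int64)
        h = np.zeros(n - L + 1, dtype=np.int64)
        for i in range(L):
            h = (h << 2) | (c[i : i + n - L + 1] & 3)
        bad = (codes >= REF_N).astype(np.int64)
        cs = np.concatenate(([0], np.cumsum(bad)))
        clean = (cs[L:] - cs[:-L]) == 0
        pos = np.flatnonzero(clean)
        return h[pos], pos

    @staticmethod
    def _pack(seeds: np.ndarray) -> np.ndarray:
        """2-bit pack a (n, L) seed matrix into int64 hashes.

        Codes >= 4 alias onto real bases; such seeds can never verify, so the
        stray candidates they produce are filtered downstream.
        """
        h = np.zeros(seeds.shape[0], dtype=np.int64)
        for i in range(seeds.shape[1]):
            h = (h << 2) | (seeds[:, i].astype(np.int64) & 3)
        return h

    def lookup_seed(self, seed: str) -> list[tuple[str, int]]:
        """Locations of one exact seed: (genome name, 0-based offset) pairs."""
        from ._codec import encode_read

        codes = encode_read(seed)
        if codes.size != self.seed_length:
            raise ValueError(f"seed must have length {self.seed_length}")
        h = self._pack(codes[None, :])
        lo = np.searchsorted(self.sorted_hash, h[0], side="left")
        hi = np.searchsorted(self.sorted_hash, h[0], side="right")
        pos = np.sort(self.sorted_pos[lo:hi])
        gi = self.genome_of(pos)
        return [
            (self.names[int(g)], int(p - self.offsets[g])) for g, p in zip(gi, pos)
        ]

    def genome_of(self, gpos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.offsets, gpos, side="right") - 1

    def _candidates(self, mat: np.ndarray, seed_offsets: Sequence[int]):
        """All (read index, global alignment start) seed candidates for one
        orientation, deduplicated."""
        n, L = mat.shape
        ridx_parts, start_parts = [], []
        for off in seed_offsets:
            qh = self._pack(mat[:, off : off + self.seed_length])
            lo = np.searchsorted(self.sorted_hash, qh, side="left")
            hi = np.searchsorted(self.sorted_hash, qh, side="right")
            cnt = hi - lo
            total = int(cnt.sum())
            if total == 0:
                continue
            ridx = np.repeat(np.arange(n, dtype=np.int64), cnt)
            base = np.repeat(lo - np.concatenate(([0], np.cumsum(cnt)[:-1])), cnt)
            spos = self.sorted_pos[base + np.arange(total)]
            ridx_parts.append(ridx)
            start_parts.append(spos - off)
        if not ridx_parts:
            return (np.empty(0, np.int64),) * 2
        ridx = np.concatenate(ridx_parts)
        start = np.concatenate(start_parts)
        # bounds: inside one genome, full read window available
        keep = start >= 0
        ridx, start = ridx[keep], start[keep]
        gi = self.genome_of(start)
        keep = (start + L <= self.offsets[gi + 1]) & (start >= self.offsets[gi])
        ridx, start = ridx[keep], start[keep]
        key = ridx * np.int64(2 * self.offsets[-1] + 2) + start
        _, uniq = np.unique(key, return_index=True)
        return ridx[uniq], start[uniq]

    def map_encoded(self, reads: np.ndarray, max_mismatch: int) -> pd.DataFrame:
        """Map an (n, L) encoded read matrix; returns one row per alignment.

        Columns: ``read_idx, genome_idx, position, strand, mismatches``.
        Reads shorter than ``(k+1) * seed_length`` cannot be mapped with the
        completeness guarantee and are reported unmapped with a warning.
        """
        if reads.ndim != 2:
            raise ValueError("expected an (n_reads, read_length) matrix")
        n, L = reads.shape
        k = int(max_mismatch)
        if k < 0:
            raise ValueError("max_mismatch must be >= 0")
        empty = pd.DataFrame(
            {
                "read_idx": np.empty(0, np.int64),
                "genome_idx": np.empty(0, np.int64),
                "position": np.empty(0, np.int64),
                "strand": np.empty(0, np.int8),
                "mismatches": np.empty(0, np.int64),
            }
        )
        if n == 0:
            return empty
        if L < (k + 1) * self.seed_length:
            log.warning(
                "reads of length %d cannot be mapped at k=%d with seed length "
                "%d; reporting them unmapped", L, k, self.seed_length,
            )
            return empty
        seed_offsets = [i * L // (k + 1) for i in range(k + 1)]

        out = []
        for strand, mat in ((0, reads), (1, np.ascontiguousarray(revcomp(reads)))):
            ridx, start = self._candidates(mat, seed_offsets)
            for lo in range(0, ridx.size, _VERIFY_CHUNK):
                sl = slice(lo, lo + _VERIFY_CHUNK)
                r, s = ridx[sl], start[sl]
                windows = self.codes[s[:, None] + np.arange(L)]
                mm = (windows != mat[r]).sum(axis=1)
                ok = mm <= k
                r, s, mm = r[ok], s[ok], mm[ok]
                gi = self.genome_of(s)
                out.append(
                    pd.DataFrame(
                        {
                            "read_idx": r,
                            "genome_idx": gi,
                            "position": s - self.offsets[gi],
                            "strand": np.full(r.size, strand, dtype=np.int8),
                            "mismatches": mm.astype(np.int64),
                        }
                    )
                )
        if not out:
            return empty
        return pd.concat(out, ignore_index=True)

    def map_sequences(
        self, seqs: Sequence[str], max_mismatch: int
    ) -> pd.DataFrame:
        """Map arbitrary-length sequences (grouped internally by length)."""
        lengths = np.array([len(s) for s in seqs])
        frames = []
        for L in np.unique(lengths):
            idx = np.flatnonzero(lengths == L)
            mat = np.vstack([encode_read(seqs[i]) for i in idx])
            df = self.map_encoded(mat, max_mismatch)
            df["read_idx"] = idx[df["read_idx"].to_numpy()]
            frames.append(df)
        if not frames:
            return self.map_encoded(np.empty((0, 1), np.uint8), max_mismatch)
        return pd.concat(frames, ignore_index=True).sort_values(
            ["read_idx", "genome_idx", "position", "strand"], ignore_index=True
        )


def build_index(panel: GenomePanel, seed_length: int = 20, **kw) -> SeedIndex:
    """Build a :class:`SeedIndex` over a panel (see class docs)."""
    return SeedIndex(panel, seed_length=seed_length, **kw)


def map_read(
    read: str, index: SeedIndex, max_mismatch: int, read_id: str = "read"
) -> set[Alignment]:
    """Map a single read; returns every alignment within the allowance."""
    df = index.map_sequences([read], max_mismatch)
    return {
        Alignment(
            read_id,
            index.names[int(row.genome_idx)],
            int(row.position),
            "-" if row.strand else "+",
            int(row.mismatches),
        )
        for row in df.itertuples()
    }


def write_sam(
    alignments: Iterable[Alignment],
    panel: GenomePanel,
    path: str | Path,
    sequences: dict[str, str] | None = None,
    unmapped_ids: Sequence[str] = (),
) -> Path:
    """Write alignments as SAM 1.x with @SQ headers and NM tags.

    ``sequences`` optionally maps read id to the original read sequence; SAM
    stores the forward-genome orientation, so minus-strand records carry the
    reverse complement.
    """
    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": g.name, "LN": len(g)} for g in panel],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        tid = {g.name: i for i, g in enumerate(panel)}
        for aln in alignments:
            seg = pysam.AlignedSegment(sam.header)
            seg.query_name = aln.read_id
            seg.reference_id = tid[aln.genome]
            seg.reference_start = aln.position
            seg.mapping_quality = 255
            seg.flag = 16 if aln.strand == "-" else 0
            if sequences and aln.read_id in sequences:
                seq = sequences[aln.read_id]
                if aln.strand == "-":
                    seq = decode(revcomp(encode_read(seq)))
                seg.query_sequence = seq
                seg.cigarstring = f"{len(seq)}M"
            else:
                # htslib demands a CIGAR for mapped records even with SEQ '*'
                seg.cigarstring = "1M"
            seg.set_tag("NM", int(aln.mismatches))
            sam.write(seg)
        for rid in unmapped_ids:
            seg = pysam.AlignedSegment(sam.header)
            seg.query_name = rid
            seg.flag = 4
            seg.reference_id = -1
            seg.mapping_quality = 0
            if sequences and rid in sequences:
                seg.query_sequence = sequences[rid]
            sam.write(seg)
    return path


def read_sam(
    path: str | Path, panel_names: Sequence[str] | None = None
) -> tuple[list[Alignment], list[str]]:
    """Read a SAM file into alignments plus the list of unmapped read ids.

    Requires @SQ headers; records mapped to genomes outside ``panel_names``
    (when given) are rejected. Mismatch counts are taken from NM tags
    (0 when absent).
    """
    path = Path(path)
    try:
        sam = pysam.AlignmentFile(str(path), "r", check_sq=True)
    except ValueError as e:
        raise ValueError(f"{path}: missing or invalid @SQ headers ({e})") from e
    alignments: list[Alignment] = []
    unmapped: list[str] = []
    with sam:
        refs = set(sam.references)
        if panel_names is not None:
            extra = refs - set(panel_names)
            if extra:
                raise ValueError(
                    f"{path}: SAM references outside the panel: {sorted(extra)}"
                )
        for lineno, rec in enumerate(sam, start=len(sam.header.to_dict().get("SQ", [])) + 2):
            try:
                if rec.is_unmapped:
                    unmapped.append(rec.query_name)
                    continue
                nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                alignments.append(
                    Alignment(
                        rec.query_name,
                        rec.reference_name,
                        int(rec.reference_start),
                        "-" if rec.is_reverse else "+",
                        int(nm),
                    )
                )
            except Exception as e:  # pragma: no cover - defensive
                raise ValueError(f"{path}: malformed record near line {lineno}: {e}") from e
    return alignments, unmapped
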