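"""Read-counting species quantification.

The core of the method: reads are mapped against the panel in one or more
rounds of increasing mismatch allowance; reads hitting exactly one genome
("unique") are counted directly, reads hitting several ("multi-mapped") are
redistributed among their candidate genomes in proportion to the unique-read
counts, the totals are corrected by each reference's completeness factor
``f = (n + c) / c``, and the result is reported as percentages alongside the
declared composition when one is supplied.

Two named strategies mirror the trade-off between specificity and
quantification accuracy: ``spec`` maps once with zero mismatches; ``quant``
iterates over allowances 0, 1, 2 and 3, each round re-attempting only the
reads left unmapped by the previous one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mapper import Alignment, SeedIndex
from .synthgen import TaggedReadSet

log = logging.getLogger(__name__)

__all__ = [
    "QuantConfig",
    "AssignmentTable",
    "ProportionReport",
    "iterative_map",
    "assignment_from_alignments",
    "redistribute_multi",
    "quality_correct",
    "proportions",
    "accuracy_from_truth",
    "saturation_curve",
]

STRATEGY_SCHEDULES = {"spec": (0,), "quant": (0, 1, 2, 3)}


@dataclass(frozen=True)
class QuantConfig:
    """Quantification strategy settings.

    ``mismatch_schedule`` defaults from the strategy name: ``spec`` -> (0,),
    ``quant`` -> (0, 1, 2, 3). A custom schedule must be strictly increasing.
    """

    strategy: str = "quant"
    mismatch_schedule: tuple[int, ...] | None = None
    apply_quality_factor: bool = True
    size_normalize: bool = False

    def __post_init__(self) -> None:
        if self.mismatch_schedule is None:
            if self.strategy not in STRATEGY_SCHEDULES:
                raise ValueError(f"unknown strategy {self.strategy!r}")
            object.__setattr__(
                self, "mismatch_schedule", STRATEGY_SCHEDULES[self.strategy]
            )
        sched = tuple(self.mismatch_schedule)
        object.__setattr__(self, "mismatch_schedule", sched)
        if not sched:
            raise ValueError("mismatch schedule must be non-empty")
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("mismatch schedule must be strictly increasing")


class AssignmentTable:
    """Per-read outcome of the mapping stage.

    Each read is exactly one of: unique (one candidate genome), multi
    (two or more), or unmapped. The candidate genome set is stored as a
    bitmask over panel genomes; ``round_idx`` records the first schedule
    entry at which the read mapped (-1 for unmapped).
    """

    def __init__(
        self,
        read_ids: np.ndarray,
        mask: np.ndarray,
        round_idx: np.ndarray,
        panel_names: Sequence[str],
    ):
        if len({*read_ids}) != len(read_ids):
            raise ValueError("duplicate read ids")
        self.read_ids = np.asarray(read_ids, dtype=object)
        self.mask = np.asarray(mask, dtype=np.int64)
        self.round_idx = np.asarray(round_idx, dtype=np.int16)
        self.panel_names = list(panel_names)

    def __len__(self) -> int:
        return int(self.read_ids.size)

    @property
    def popcount(self) -> np.ndarray:
        return np.bitwise_count(self.mask.astype(np.uint64)).astype(np.int64)

    @property
    def is_unique(self) -> np.ndarray:
        return self.popcount == 1

    @property
    def is_multi(self) -> np.ndarray:
        return self.popcount >= 2

    @property
    def is_unmapped(self) -> np.ndarray:
        return self.mask == 0

    def status_counts(self) -> dict[str, int]:
        return {
            "unique": int(self.is_unique.sum()),
            "multi": int(self.is_multi.sum()),
            "unmapped": int(self.is_unmapped.sum()),
        }

    def unique_genome_idx(self) -> np.ndarray:
        """For unique reads, the index of their single candidate genome."""
        m = self.mask[self.is_unique].astype(np.uint64)
        # masks are single-bit; exact log2 via float is safe below 2**53
        return np.log2(m.astype(np.float64)).astype(np.int64)

    def unique_counts(self) -> pd.Series:
        """Cumulative unique-read count per genome over all rounds."""
        counts = np.zeros(len(self.panel_names), dtype=np.int64)
        idx, c = np.unique(self.unique_genome_idx(), return_counts=True)
        counts[idx] = c
        return pd.Series(counts, index=self.panel_names, name="unique")

    def genome_sets(self) -> list[frozenset[str]]:
        names = np.array(self.panel_names, dtype=object)
        return [
            frozenset(names[[i for i in range(len(names)) if m >> i & 1]])
            for m in self.mask
        ]


def iterative_map(
    reads: TaggedReadSet, index: SeedIndex, config: QuantConfig
) -> AssignmentTable:
    """Map a read set through the strategy's mismatch schedule.

    Round ``j`` maps only the reads left unmapped by rounds ``< j``, at the
    allowance ``schedule[j]``. Residual unmapped reads stay marked for export
    to the metagenomic stage.
    """
    n = len(reads)
    mask = np.zeros(n, dtype=np.int64)
    rounds = np.full(n, -1, dtype=np.int16)
    remaining = np.arange(n)
    for j, k in enumerate(config.mismatch_schedule):
        if remaining.size == 0:
            break
        hits = index.map_encoded(reads.codes[remaining], k)
        if len(hits):
            local_mask = np.zeros(remaining.size, dtype=np.int64)
            bits = np.int64(1) << hits["genome_idx"].to_numpy()
            np.bitwise_or.at(local_mask, hits["read_idx"].to_numpy(), bits)
            mapped = local_mask != 0
            mask[remaining[mapped]] = local_mask[mapped]
            rounds[remaining[mapped]] = j
            remaining = remaining[~mapped]
    return AssignmentTable(reads.ids, mask, rounds, index.names)


def assignment_from_alignments(
    rounds: Sequence[Sequence[Alignment]],
    all_read_ids: Sequence[str],
    panel_names: Sequence[str],
) -> AssignmentTable:
    """Build an assignment table from externally produced alignments.

    ``rounds`` is one alignment collection per mapping round (e.g. parsed
    from per-round SAM files); a read is resolved in the first round where it
    has at least one alignment, consistent with iterative mapping.
    """
    ids = np.asarray(list(all_read_ids), dtype=object)
    pos = {rid: i for i, rid in enumerate(ids)}
    gidx = {name: i for i, name in enumerate(panel_names)}
    mask = np.zeros(ids.size, dtype=np.int64)
    round_idx = np.full(ids.size, -1, dtype=np.int16)
    for j, alns in enumerate(rounds):
        for aln in alns:
            if aln.read_id not in pos:
                raise ValueError(f"alignment for unknown read {aln.read_id!r}")
            i = pos[aln.read_id]
            if round_idx[i] != -1 and round_idx[i] != j:
                continue  # resolved in an earlier round
            mask[i] |= np.int64(1) << gidx[aln.genome]
            round_idx[i] = j
    return AssignmentTable(ids, mask, round_idx, panel_names)


def redistribute_multi(table: AssignmentTable) -> pd.Series:
    """Augment unique counts with proportional shares of multi-mapped reads.

    Each multi-mapped read with candidate set S contributes weight
    ``U_g / sum(U_h for h in S)`` to every genome g in S, where U are the
    cumulative unique counts pooled over all rounds. A candidate set whose
    unique counts are all zero is split evenly (logged). The augmented total
    equals unique + multi exactly.
    """
    U = table.unique_counts().to_numpy().astype(float)
    aug = U.copy()
    multi_masks, counts = np.unique(
        table.mask[table.is_multi], return_counts=True
    )
    G = len(table.panel_names)
    for m, c in zip(multi_masks, counts):
        members = np.array([i for i in range(G) if m >> i & 1])
        denom = U[members].sum()
        if denom == 0:
            log.warning(
                "multi-mapped reads over %s have no unique support; splitting evenly",
                [table.panel_names[i] for i in members],
            )
            aug[members] += c / members.size
        else:
            aug[members] += c * U[members] / denom
    return pd.Series(aug, index=table.panel_names, name="augmented")


def quality_correct(
    counts: pd.Series, quality: pd.DataFrame, apply: bool = True
) -> pd.Series:
    """Scale counts by the genome quality factor ``f = (n + c) / c``.

    ``quality`` is the frame produced by :meth:`GenomePanel.quality`. Applied
    after redistribution; a no-op when ``apply`` is false.
    """
    if not apply:
        return counts.astype(float)
    missing = counts.index.difference(quality.index)
    if len(missing):
        raise ValueError(f"no quality record for genomes: {list(missing)}")
    return counts.astype(float) * quality.loc[counts.index, "f"]


@dataclass
class ProportionReport:
    """Per-species proportions with optional declared-composition columns.

    ``table`` columns: reads_assigned, proportion_pct and, when targets were
    given, target_pct, diff_abs_pct, diff_rel_pct (NaN where the target is 0,
    rendered as ``n.a.``). ``raw_total`` is the uncorrected sum of counts
    before renormalization to 100%.
    """

    table: pd.DataFrame
    raw_total: float

    @property
    def proportions(self) -> pd.Series:
        return self.table["proportion_pct"]

    @property
    def max_abs_diff(self) -> float:
        return float(self.table["diff_abs_pct"].max())

    @property
    def max_rel_diff(self) -> float:
        return float(self.table["diff_rel_pct"].max())

    def sum_abs_deviation(self) -> float:
        return float(self.table["diff_abs_pct"].sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        if "diff_rel_pct" in out:
            out["diff_rel_pct"] = [
                "n.a." if pd.isna(v) else v for v in out["diff_rel_pct"]
            ]
        return out

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g")
        return path

    def to_json(self, path: str | Path) -> Path:
        import json

        path = Path(path)
        payload = {
            "raw_total": self.raw_total,
            "species": self.to_frame().reset_index().to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


def proportions(
    counts: pd.Series,
    targets: Mapping[str, float] | None = None,
    genome_lengths: Mapping[str, int] | None = None,
    size_normalize: bool = False,
) -> ProportionReport:
    """Turn (corrected) per-genome counts into a proportion report.

    Species present in ``targets`` but absent from ``counts`` appear with
    zero reads, so an omitted reference genome shows a proportion of 0% and
    an absolute difference equal to its declared share. With
    ``size_normalize`` counts are divided by genome length first (off by
    default).
    """
    counts = counts.astype(float)
    if targets is not None:
        missing = [s for s in targets if s not in counts.index]
        if missing:
            counts = pd.concat([counts, pd.Series(0.0, index=missing)])
    if size_normalize:
        if genome_lengths is None:
            raise ValueError("size_normalize requires genome_lengths")
        lens = pd.Series({s: genome_lengths.get(s, np.nan) for s in counts.index})
        counts = counts / lens
    total = counts.sum()
    if total <= 0:
        raise ValueError("all counts are zero; nothing to report")
    tab = pd.DataFrame(
        {
            "reads_assigned": counts,
            "proportion_pct": counts / total * 100.0,
        }
    )
    tab.index.name = "species"
    if targets is not None:
        tab["target_pct"] = pd.Series(dict(targets)).reindex(tab.index)
        tab["diff_abs_pct"] = (tab["proportion_pct"] - tab["target_pct"]).abs()
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = tab["diff_abs_pct"] / tab["target_pct"] * 100.0
        tab["diff_rel_pct"] = rel.where(tab["target_pct"] > 0)
    return ProportionReport(table=tab, raw_total=float(total))


def accuracy_from_truth(
    table: AssignmentTable, origins: np.ndarray
) -> tuple[float, pd.Series]:
    """Unique-read mapping accuracy against ground-truth origin tags.

    Returns (overall accuracy %, per-origin-species accuracy %): the fraction
    of uniquely mapped reads whose assigned genome equals their true origin.
    """
    if origins is None:
        raise ValueError("reads carry no ground-truth tags")
    origins = np.asarray(origins, dtype=object)
    uniq = table.is_unique
    if not uniq.any():
        raise ValueError("no uniquely mapped reads")
    assigned = np.array(table.panel_names, dtype=object)[table.unique_genome_idx()]
    truth = origins[uniq]
    correct = assigned == truth
    overall = float(correct.mean() * 100.0)
    per = (
        pd.DataFrame({"origin": truth, "correct": correct})
        .groupby("origin")["correct"]
        .mean()
        * 100.0
    )
    return overall, per.rename("accuracy_pct")


def run_quant(
    reads: TaggedReadSet,
    index: SeedIndex,
    config: QuantConfig,
    targets: Mapping[str, float] | None = None,
    quality: pd.DataFrame | None = None,
    genome_lengths: Mapping[str, int] | None = None,
) -> tuple[AssignmentTable, ProportionReport]:
    """Convenience wrapper: map -> redistribute -> correct -> proportions."""
    table = iterative_map(reads, index, config)
    counts = redistribute_multi(table)
    if config.apply_quality_factor:
        if quality is None:
            raise ValueError("apply_quality_factor requires a quality table")
        counts = quality_correct(counts, quality)
    report = proportions(
        counts, targets, genome_lengths, size_normalize=config.size_normalize
    )
    return table, report


def saturation_curve(
    reads: TaggedReadSet,
    index: SeedIndex,
    config: QuantConfig,
    targets: Mapping[str, float],
    sizes: Sequence[int],
    replicates: int = 3,
    seed: int = 0,
    quality: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Summed absolute proportion deviation versus read subsample size.

    For each size, ``replicates`` subsamples are drawn without replacement
    (fresh random stream per replicate), the full quantification is re-run and
    ``sum_g |observed_g - target_g|`` recorded. A size equal to the whole pool
    is computed once (every subsample would be the full pool). Returns a frame
    with columns size, mean_deviation, sd_deviation.
    """
    sizes = list(sizes)
    if any(s > len(reads) for s in sizes):
        raise ValueError("subsample size exceeds the read pool")
    rows = []
    for si, size in enumerate(sizes):
        reps = 1 if size == len(reads) else replicates
        devs = []
        for r in range(reps):
            rng = np.random.default_rng([seed, si, r])
            sub = reads if size == len(reads) else reads.subsample(size, rng)
            _, report = run_quant(sub, index, config, targets=targets, quality=quality)
            devs.append(report.sum_abs_deviation())
        devs = np.array(devs)
        rows.append((size, float(devs.mean()), float(devs.std(ddof=1)) if reps > 1 else 0.0))
    return pd.DataFrame(rows, columns=["size", "mean_deviation", "sd_deviation"])
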