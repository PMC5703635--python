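"""File formats: popoolation2-style sync files and a simple trajectory TSV.

Readers reject inconsistent data rather than silently repairing it; the
sync reader turns per-sample A:T:C:G:N:del count sextets into biallelic
(variant reads, depth) trajectories, excluding N and deletion counts from
the depth.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .hmm import AlleleTrajectory, TrajectorySet

__all__ = ["read_sync", "read_trajectory_tsv", "write_trajectory_tsv"]

logger = logging.getLogger(__name__)

_BASES = ("A", "T", "C", "G")  # sync column order A:T:C:G:N:del

TSV_COLUMNS = ["locus_id", "generation", "n", "C"]


def read_sync(
    path,
    sample_to_time_map: Mapping[int, int] | Sequence[int],
    focal_allele_rule: str = "major-at-t1",
    explicit_alleles: Mapping[str, str] | None = None,
) -> TrajectorySet:
    """Read a sync file into per-locus trajectories.

    ``sample_to_time_map`` maps sample column index (0-based, in file
    order) to sampling generation; a plain sequence assigns generations to
    columns in order.  The focal allele per locus is chosen by
    ``focal_allele_rule``: the major or minor allele at the earliest
    generation, or ``"explicit"`` with a {"chrom:pos": base} mapping.
    Loci monomorphic across all samples are dropped (count logged).
    """
    if isinstance(sample_to_time_map, Mapping):
        col_times = dict(sample_to_time_map)
    else:
        col_times = {i: t for i, t in enumerate(sample_to_time_map)}
    if not col_times:
        raise ValueError("sample_to_time_map must not be empty")
    if focal_allele_rule not in ("major-at-t1", "minor-at-t1", "explicit"):
        raise ValueError(f"unknown focal allele rule {focal_allele_rule!r}")
    if focal_allele_rule == "explicit" and not explicit_alleles:
        raise ValueError("explicit rule requires an explicit_alleles mapping")

    order = sorted(col_times, key=col_times.get)
    times = [col_times[c] for c in order]
    first_col = order[0]

    trajs = []
    n_mono = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3 + max(col_times) + 1:
                raise ValueError(f"{path}:{lineno}: expected at least {3 + max(col_times) + 1} columns")
            chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad position {pos_s!r}") from None
            if pos < 1:
                raise ValueError(f"{path}:{lineno}: position must be >= 1")
            if ref not in _BASES + ("N",):
                raise ValueError(f"{path}:{lineno}: unknown reference base {ref!r}")

            counts = []
            for c in order:
                sextet = fields[3 + c].split(":")
                if len(sextet) != 6:
                    raise ValueError(f"{path}:{lineno}: malformed count column {fields[3 + c]!r}")
                try:
                    vals = [int(v) for v in sextet]
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-integer count in {fields[3 + c]!r}") from None
                if any(v < 0 for v in vals):
                    raise ValueError(f"{path}:{lineno}: negative count")
                counts.append(vals)

            base_counts_t1 = dict(zip(_BASES, counts[0][:4]))
            locus = f"{chrom}:{pos}"
            if focal_allele_rule == "explicit":
                focal = explicit_alleles.get(locus)
                if focal is None or focal.upper() not in _BASES:
                    raise ValueError(f"{path}:{lineno}: no explicit focal allele for {locus}")
                focal = focal.upper()
            else:
                ranked = sorted(_BASES, key=lambda b: (-base_counts_t1[b], b))
                present = [b for b in _BASES if base_counts_t1[b] > 0]
                if focal_allele_rule == "major-at-t1":
                    focal = ranked[0]
                else:
                    focal = min(present, key=lambda b: (base_counts_t1[b], b)) if present else ranked[-1]

            fi = _BASES.index(focal)
            n = [c[fi] for c in counts]
            C = [sum(c[:4]) for c in counts]
            freqs = {ni / Ci for ni, Ci in zip(n, C) if Ci > 0}
            if freqs <= {0.0} or freqs <= {1.0}:
                n_mono += 1
                continue
            trajs.append(AlleleTrajectory(locus, tuple(times), tuple(n), tuple(C)))

    if n_mono:
        logger.info("read_sync: dropped %d monomorphic loci", n_mono)
    if not trajs:
        raise ValueError(f"{path}: no polymorphic loci found")
    return TrajectorySet(trajs)


def read_trajectory_tsv(path) -> TrajectorySet:
    """Read a trajectory TSV with columns locus_id, generation, n, C.

    Rows are sorted by generation within each locus; duplicate
    (locus, generation) rows and n > C are errors.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: no trajectory rows")
    bad = df[df["n"] > df["C"]]
    if not bad.empty:
        raise ValueError(f"{path}: n > C at row(s) {bad.index.tolist()}")
    dupes = df.duplicated(subset=["locus_id", "generation"])
    if dupes.any():
        raise ValueError(
            f"{path}: duplicate (locus, generation) rows at {df.index[dupes].tolist()}"
        )
    trajs = []
    for locus, sub in df.groupby("locus_id", sort=False):
        sub = sub.sort_values("generation")
        trajs.append(
            AlleleTrajectory(
                str(locus),
                tuple(sub["generation"].astype(int)),
                tuple(sub["n"].astype(int)),
                tuple(sub["C"].astype(int)),
            )
        )
    return TrajectorySet(trajs)


def write_trajectory_tsv(data: TrajectorySet, path) -> None:
    """Write a TrajectorySet to the TSV format read_trajectory_tsv accepts."""
    rows = [
        (t.locus_id, g, n, C)
        for t in data
        for g, n, C in zip(t.times, t.n, t.C)
    ]
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)
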