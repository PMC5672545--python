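"""Probe-panel read counting for targeted RNA-seq.

Targeted assays (e.g. TempO-Seq) read out fixed-length detector probes, so a
demultiplexed FASTQ can be assigned directly against the probe manifest: each
read's first ``L`` bases are matched to the 50-mer probe with the smallest
Hamming distance.  An exact-match hash covers the bulk of reads; only the
remainder is scanned against the full panel.  Counts are reported per probe
and aggregated per gene (sum over a gene's probes).
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

UNASSIGNED = "UNASSIGNED"

_DNA_RE = re.compile(r"^[ACGT]+$")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ManifestError(ValueError):
    """Raised when a probe manifest fails validation."""


@dataclass
class ProbeManifest:
    """Validated probe panel: ids, gene symbols and fixed-length sequences."""

    probe_ids: list[str]
    gene_symbols: list[str]
    sequences: list[str]

    # internal lookup structures, built lazily
    _exact: dict[str, int] = field(default_factory=dict, repr=False)
    _seq_matrix: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.probe_ids)
        if not (n == len(self.gene_symbols) == len(self.sequences)):
            raise ManifestError("probe_ids, gene_symbols and sequences must align")
        if n == 0:
            raise ManifestError("manifest is empty")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ManifestError(f"probe sequences have mixed lengths: {sorted(lengths)}")
        seen: dict[str, int] = {}
        for i, pid in enumerate(self.probe_ids):
            if pid in seen:
                raise ManifestError(f"duplicate probe id {pid!r} (rows {seen[pid]} and {i})")
            seen[pid] = i
        for i, seq in enumerate(self.sequences):
            if not _DNA_RE.match(seq):
                raise ManifestError(
                    f"probe {self.probe_ids[i]!r} (row {i}): sequence contains non-ACGT characters"
                )
        # duplicate sequences are legal but ambiguous; warn once with the ids
        by_seq: dict[str, list[str]] = {}
        for pid, seq in zip(self.probe_ids, self.sequences):
            by_seq.setdefault(seq, []).append(pid)
        dups = {s: ids for s, ids in by_seq.items() if len(ids) > 1}
        if dups:
            detail = "; ".join(", ".join(ids) for ids in dups.values())
            warnings.warn(
                f"{len(dups)} probe sequence(s) shared by multiple probes: {detail}",
                stacklevel=2,
            )
        first_row = {pid: i for i, pid in reversed(list(enumerate(self.probe_ids)))}
        gene_of = dict(zip(self.probe_ids, self.gene_symbols))
        for seq, ids in by_seq.items():
            # sequences shared across genes stay out of the exact map so the
            # Hamming path can flag them ambiguous (distance-0 cross-gene tie)
            if len({gene_of[i] for i in ids}) == 1:
                self._exact[seq] = first_row[ids[0]]

    @property
    def length(self) -> int:
        """Probe length L (typically 50)."""
        return len(self.sequences[0])

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def genes(self) -> list[str]:
        """Unique gene symbols in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.gene_symbols:
            seen.setdefault(g, None)
        return list(seen)

    def seq_matrix(self) -> np.ndarray:
        """Probe sequences as a (n_probes, L) uint8 byte matrix."""
        if self._seq_matrix is None:
            self._seq_matrix = np.frombuffer(
                "".join(self.sequences).encode(), dtype=np.uint8
            ).reshape(self.n_probes, self.length)
        return self._seq_matrix


@dataclass
class ReadAssignment:
    read_id: str
    probe_id: str  # UNASSIGNED when no probe qualifies
    mismatches: int  # -1 when unassigned
    status: str  # assigned | ambiguous | unassigned | short


def parse_manifest(
    path: str | Path,
    probe_col: str = "probe_id",
    gene_col: str = "gene_symbol",
    seq_col: str = "sequence",
) -> ProbeManifest:
    """Parse a probe manifest CSV into a validated :class:`ProbeManifest`.

    Column names are configurable; matching is case-insensitive.  Sequences
    are upper-cased before validation.
    """
    df = pd.read_csv(path, dtype=str)
    lower = {c.lower(): c for c in df.columns}
    cols = {}
    for want in (probe_col, gene_col, seq_col):
        if want in df.columns:
            cols[want] = want
        elif want.lower() in lower:
            cols[want] = lower[want.lower()]
        else:
            raise ManifestError(f"manifest {path} is missing required column {want!r}")
    return ProbeManifest(
        probe_ids=df[cols[probe_col]].astype(str).tolist(),
        gene_symbols=df[cols[gene_col]].astype(str).tolist(),
        sequences=df[cols[seq_col]].astype(str).str.upper().tolist(),
    )


def assign_read(
    read: str,
    manifest: ProbeManifest,
    max_mismatch: int = 2,
    read_id: str = "",
    search_revcomp: bool = False,
) -> ReadAssignment:
    """Assign a single read to the closest probe by Hamming distance.

    The first ``L`` bases of the read are compared to every probe; the probe
    with the minimum distance wins when that distance is ``<= max_mismatch``.
    A tie between probes of *different* genes is ambiguous (gene-level counts
    are the downstream unit, so same-gene ties still resolve to the gene);
    reads shorter than ``L`` are flagged short.
    """
    L = manifest.length
    read = read.upper()
    if len(read) < L:
        return ReadAssignment(read_id, UNASSIGNED, -1, "short")
    prefix = read[:L]
    hit = manifest._exact.get(prefix)
    if hit is not None:
        return ReadAssignment(read_id, manifest.probe_ids[hit], 0, "assigned")
    candidates = [prefix]
    if search_revcomp:
        candidates.append(_revcomp(read)[:L])
    best: ReadAssignment | None = None
    for cand in candidates:
        arr = np.frombuffer(cand.encode(), dtype=np.uint8)
        dists = (manifest.seq_matrix() != arr).sum(axis=1)
        a = _resolve(dists, manifest, max_mismatch, read_id)
        if best is None or (
            a.status == "assigned"
            and (best.status != "assigned" or a.mismatches < best.mismatches)
        ):
            best = a
    return best  # type: ignore[return-value]


def _resolve(
    dists: np.ndarray, manifest: ProbeManifest, max_mismatch: int, read_id: str
) -> ReadAssignment:
    d = int(dists.min())
    if d > max_mismatch:
        return ReadAssignment(read_id, UNASSIGNED, -1, "unassigned")
    idx = np.flatnonzero(dists == d)
    genes = {manifest.gene_symbols[i] for i in idx}
    if len(genes) > 1:
        return ReadAssignment(read_id, UNASSIGNED, d, "ambiguous")
    return ReadAssignment(read_id, manifest.probe_ids[int(idx[0])], d, "assigned")


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(path: Path) -> Iterable[tuple[str, str, str]]:
    with _open_maybe_gz(path) as fh:
        yield from FastqGeneralIterator(fh)


_FASTQ_SUFFIXES = (".fastq", ".fq", ".fastq.gz", ".fq.gz")


def sample_id_from_path(path: Path) -> str:
    name = path.name
    for suf in _FASTQ_SUFFIXES:
        if name.endswith(suf):
            return name[: -len(suf)]
    return path.stem


def count_fastq(
    path: str | Path,
    manifest: ProbeManifest,
    max_mismatch: int = 2,
    search_revcomp: bool = False,
    min_mean_q: float | None = None,
) -> tuple[np.ndarray, dict[str, int]]:
    """Count probe assignments for one FASTQ file.

    Returns (per-probe count vector, summary dict).  The summary conserves
    reads: assigned + ambiguous + unassigned + short (+ low_quality when the
    mean-Q filter is enabled) = total.
    """
    path = Path(path)
    L = manifest.length
    counts = np.zeros(manifest.n_probes, dtype=np.int64)
    summary = {"total": 0, "assigned": 0, "ambiguous": 0, "unassigned": 0, "short": 0}
    if min_mean_q is not None:
        summary["low_quality"] = 0
    pending: list[str] = []  # reads that missed the exact hash
    exact = manifest._exact
    probe_ids = manifest.probe_ids
    pid_index = {p: i for i, p in enumerate(probe_ids)}

    def flush() -> None:
        if not pending:
            return
        block = np.frombuffer("".join(pending).encode(), dtype=np.uint8).reshape(
            len(pending), L
        )
        # (reads, probes) mismatch counts in one broadcast
        dists = (block[:, None, :] != manifest.seq_matrix()[None, :, :]).sum(axis=2)
        for row in dists:
            a = _resolve(row, manifest, max_mismatch, "")
            summary[a.status] += 1
            if a.status == "assigned":
                counts[pid_index[a.probe_id]] += 1
        pending.clear()

    try:
        for rec_index, (title, seq, qual) in enumerate(_iter_fastq(path)):
            summary["total"] += 1
            seq = seq.upper()
            if min_mean_q is not None:
                q = np.frombuffer(qual.encode(), dtype=np.uint8) - 33
                if q.size and q.mean() < min_mean_q:
                    summary["low_quality"] += 1
                    continue
            if len(seq) < L:
                summary["short"] += 1
                continue
            prefix = seq[:L]
            hit = exact.get(prefix)
            if hit is not None:
                counts[hit] += 1
                summary["assigned"] += 1
                continue
            if search_revcomp:
                a = assign_read(seq, manifest, max_mismatch, search_revcomp=True)
                summary[a.status] += 1
                if a.status == "assigned":
                    counts[pid_index[a.probe_id]] += 1
                continue
            pending.append(prefix)
            if len(pending) >= 2048:
                flush()
    except ValueError as exc:
        raise ValueError(f"ill-formed FASTQ record in {path} near record {summary['total']}: {exc}")
    flush()
    if summary["total"] == 0:
        warnings.warn(f"FASTQ file {path} contains no reads", stacklevel=2)
    return counts, summary


@dataclass
class CountResult:
    """Probe- and gene-level count matrices plus per-sample assignment summary."""

    probe_counts: pd.DataFrame  # probes x samples
    gene_counts: pd.DataFrame  # genes x samples
    summary: pd.DataFrame  # samples x {total, assigned, ambiguous, unassigned, short}


def aggregate_to_genes(probe_counts: pd.DataFrame, manifest: ProbeManifest) -> pd.DataFrame:
    """Sum probe-level counts to gene level following the manifest mapping."""
    gene_of = pd.Series(manifest.gene_symbols, index=manifest.probe_ids)
    out = probe_counts.groupby(gene_of.reindex(probe_counts.index)).sum()
    return out.reindex(manifest.genes)


def count_directory(
    fastq_dir: str | Path,
    manifest: ProbeManifest,
    max_mismatch: int = 2,
    search_revcomp: bool = False,
    min_mean_q: float | None = None,
) -> CountResult:
    """Count every FASTQ file in a directory into one matrix.

    One file per sample; the sample id is the filename stem.  Files are
    processed in sorted order so the output is deterministic.
    """
    fastq_dir = Path(fastq_dir)
    files = sorted(
        p for p in fastq_dir.iterdir() if p.name.endswith(_FASTQ_SUFFIXES)
    )
    if not files:
        raise ValueError(f"no FASTQ files found in {fastq_dir}")
    cols: dict[str, np.ndarray] = {}
    summaries = []
    for path in files:
        sid = sample_id_from_path(path)
        counts, summary = count_fastq(
            path, manifest, max_mismatch, search_revcomp, min_mean_q
        )
        cols[sid] = counts
        summaries.append({"sample_id": sid, **summary})
    probe_counts = pd.DataFrame(cols, index=pd.Index(manifest.probe_ids, name="probe_id"))
    gene_counts = aggregate_to_genes(probe_counts, manifest)
    gene_counts.index.name = "gene"
    summary_df = pd.DataFrame(summaries).set_index("sample_id")
    return CountResult(probe_counts, gene_counts, summary_df)


def merge_counts(
    count_tables: Sequence[pd.DataFrame | pd.Series],
    manifest: ProbeManifest,
    level: str = "gene",
) -> pd.DataFrame:
    """Merge per-sample count tables into one matrix; absent features get 0.

    Each table is a single-column DataFrame (or Series) indexed by probe or
    gene id; column order in the output follows input order.
    """
    universe = manifest.genes if level == "gene" else manifest.probe_ids
    known = set(universe)
    cols = []
    for tbl in count_tables:
        s = tbl.iloc[:, 0] if isinstance(tbl, pd.DataFrame) else tbl
        unknown = [i for i in s.index if i not in known]
        if unknown:
            raise ValueError(f"unknown {level} id(s) in count table: {unknown[:5]}")
        cols.append(s.reindex(universe).fillna(0).astype(np.int64))
    out = pd.concat(cols, axis=1)
    out.index.name = level
    return out
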