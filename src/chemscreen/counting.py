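"""sgRNA counting: FASTQ -> count table, plus lossless tabular I/O.

Reads are matched to the library by exact protospacer lookup at a configured
offset (the de-facto standard for pooled screens, and deterministic); an
optional substring-scan mode searches the whole read and discards multi-hit
reads. No quality filtering or trimming is applied.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import yaml

from .library import SgRNALibrary

logger = logging.getLogger(__name__)

ROLES = ("t0", "untreated", "treated")


class FastqFormatError(ValueError):
    """Truncated or malformed FASTQ record (message carries the line number)."""


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one sequenced sample."""

    name: str
    role: str  # one of ROLES
    doublings: float | None = None  # doublings since t0, where meaningful

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"sample {self.name!r}: role must be one of {ROLES}")
        if self.doublings is not None and self.doublings < 0:
            raise ValueError(f"sample {self.name!r}: doublings must be >= 0")


@dataclass
class CountTable:
    """sgRNA x sample matrix of non-negative integer read counts.

    ``counts`` is indexed by sgrna_id (exactly the library's ids, in library
    order) with one int64 column per sample; ``unmapped`` and ``ambiguous``
    tally reads that matched nothing / more than one sgRNA (scan mode only).
    """

    counts: pd.DataFrame
    samples: dict[str, SampleInfo]
    unmapped: dict[str, int] = field(default_factory=dict)
    ambiguous: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples):
            raise ValueError("count columns and sample metadata disagree")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def samples_with_role(self, role: str) -> list[str]:
        return [s.name for s in self.samples.values() if s.role == role]

    def column(self, name: str) -> pd.Series:
        return self.counts[name]

    def total_reads(self, name: str) -> int:
        return int(self.counts[name].sum()) + self.unmapped.get(name, 0) + self.ambiguous.get(name, 0)

    # -- I/O ---------------------------------------------------------------

    def write(self, counts_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write counts TSV (first column sgrna_id) plus a YAML sidecar with
        sample roles, doubling metadata and mapping tallies."""
        counts_path = Path(counts_path)
        out = self.counts.copy()
        out.insert(0, "sgrna_id", out.index)
        out.to_csv(counts_path, sep="\t", index=False)
        if sidecar_path is None:
            sidecar_path = counts_path.with_suffix(counts_path.suffix + ".yaml")
        meta = {
            "samples": [
                {"name": s.name, "role": s.role, "doublings": s.doublings}
                for s in self.samples.values()
            ],
            "unmapped": dict(self.unmapped),
            "ambiguous": dict(self.ambiguous),
        }
        Path(sidecar_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_counts(
    counts_path: str | Path,
    library: SgRNALibrary,
    sidecar_path: str | Path | None = None,
    samples: Iterable[SampleInfo] | None = None,
) -> CountTable:
    """Read a counts TSV back into a :class:`CountTable`.

    Sample roles come from the YAML sidecar (default: ``<counts>.yaml``) or an
    explicit ``samples`` iterable. Library sgRNAs absent from the TSV are
    filled with 0 (warning); TSV sgRNAs absent from the library are an error.
    """
    counts_path = Path(counts_path)
    tab = pd.read_csv(counts_path, sep="\t", dtype={"sgrna_id": str})
    tab = tab.set_index("sgrna_id")
    for col in tab.columns:
        vals = tab[col]
        if not np.issubdtype(vals.dtype, np.number) or (vals < 0).any() or (vals != np.floor(vals)).any():
            raise ValueError(f"count column {col!r} contains negatives or non-integers")
    unknown = tab.index.difference(library.sgrna_ids)
    if len(unknown):
        raise ValueError(f"counts contain sgRNAs absent from the library: {sorted(unknown)}")
    missing = library.sgrna_ids.difference(tab.index)
    if len(missing):
        warnings.warn(
            f"{len(missing)} library sgRNAs missing from counts; filled with 0",
            stacklevel=2,
        )
    tab = tab.reindex(library.sgrna_ids, fill_value=0).astype(np.int64)
    tab.index.name = "sgrna_id"

    unmapped: dict[str, int] = {}
    ambiguous: dict[str, int] = {}
    if samples is None:
        if sidecar_path is None:
            sidecar_path = counts_path.with_suffix(counts_path.suffix + ".yaml")
        meta = yaml.safe_load(Path(sidecar_path).read_text())
        samples = [SampleInfo(**entry) for entry in meta["samples"]]
        unmapped = dict(meta.get("unmapped", {}))
        ambiguous = dict(meta.get("ambiguous", {}))
    sample_map = {s.name: s for s in samples}
    return CountTable(tab.loc[:, list(sample_map)], sample_map, unmapped, ambiguous)


# -- FASTQ parsing ---------------------------------------------------------


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_fastq_sequences(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a (possibly gzipped) FASTQ file.

    Raises :class:`FastqFormatError` with the 1-based line number on a
    truncated or malformed record.
    """
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise FastqFormatError(f"{path}: line {lineno}: expected '@' header")
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FastqFormatError(
                    f"{path}: truncated FASTQ record starting at line {lineno}"
                )
            lineno += 3
            if not plus.startswith("+"):
                raise FastqFormatError(f"{path}: line {lineno - 1}: expected '+' separator")
            yield seq.strip().upper()


def count_reads(
    sample_files: dict[str, str | Path | list[str | Path]],
    library: SgRNALibrary,
    samples: Iterable[SampleInfo],
    offset: int = 0,
    scan: bool = False,
) -> CountTable:
    """Count sgRNA-matching reads per sample.

    Parameters
    ----------
    sample_files
        Mapping sample name -> FASTQ path (or list of paths).
    offset
        0-based position of the protospacer within each read (exact-match mode).
    scan
        If True, search the protospacer anywhere in the read; reads matching
        more than one sgRNA are discarded into the ``ambiguous`` tally.

    A read increments an sgRNA iff its substring matches the protospacer
    exactly; everything else increments ``unmapped``. Totals are conserved:
    mapped + unmapped (+ ambiguous) == reads seen.
    """
    samples = list(samples)
    sample_map = {s.name: s for s in samples}
    if set(sample_files) != set(sample_map):
        raise ValueError("sample_files and samples must name the same samples")
    seq_to_id = library.sequence_index()
    L = library.protospacer_length
    ids = library.sgrna_ids

    mat = pd.DataFrame(0, index=ids, columns=list(sample_map), dtype=np.int64)
    mat.index.name = "sgrna_id"
    unmapped: dict[str, int] = {}
    ambiguous: dict[str, int] = {}

    for name in sample_map:
        paths = sample_files[name]
        if isinstance(paths, (str, Path)):
            paths = [paths]
        tally: dict[str, int] = {}
        n_unmapped = 0
        n_ambig = 0
        for path in paths:
            for read in iter_fastq_sequences(path):
                if len(read) < offset + L:
                    n_unmapped += 1
                    continue
                if not scan:
                    sg = seq_to_id.get(read[offset : offset + L])
                    if sg is None:
                        n_unmapped += 1
                    else:
                        tally[sg] = tally.get(sg, 0) + 1
                else:
                    hits = {
                        seq_to_id[read[i : i + L]]
                        for i in range(len(read) - L + 1)
                        if read[i : i + L] in seq_to_id
                    }
                    if not hits:
                        n_unmapped += 1
                    elif len(hits) > 1:
                        n_ambig += 1
                    else:
                        sg = hits.pop()
                        tally[sg] = tally.get(sg, 0) + 1
        if tally:
            col = pd.Series(tally, dtype=np.int64).reindex(ids, fill_value=0)
            mat[name] = col.to_numpy()
        unmapped[name] = n_unmapped
        ambiguous[name] = n_ambig
        logger.info(
            "sample %s: %d mapped, %d unmapped, %d ambiguous",
            name, int(mat[name].sum()), n_unmapped, n_ambig,
        )
    return CountTable(mat, sample_map, unmapped, ambiguous)


def mapping_stats(table: CountTable) -> dict:
    """Per-sample total/mapped/unmapped(/ambiguous) read tallies as a dict."""
    stats = {}
    for name in table.samples:
        mapped = int(table.counts[name].sum())
        stats[name] = {
            "mapped": mapped,
            "unmapped": table.unmapped.get(name, 0),
            "ambiguous": table.ambiguous.get(name, 0),
            "total": table.total_reads(name),
        }
    return stats
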