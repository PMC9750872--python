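"""sgRNA library reference table.

The library is the ground truth against which sequencing reads are counted and
sgRNAs are grouped into genes/TSSs. Non-targeting control sgRNAs (no genomic
target) carry a reserved sentinel gene/TSS label and define the null
distribution for every downstream normalization and test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Sentinel gene / TSS labels carried by every non-targeting record.
NONTARGETING_GENE = "non-targeting"
NONTARGETING_TSS = "na"

LIBRARY_COLUMNS = ["sgrna_id", "sequence", "gene", "tss", "is_nontargeting"]

_VALID_BASES = frozenset("ACGT")


class LibraryError(ValueError):
    """Raised when a library violates its invariants (named records included)."""


@dataclass(frozen=True)
class SgRNALibrary:
    """Validated sgRNA reference table.

    Attributes
    ----------
    table : pandas.DataFrame
        Columns ``sgrna_id, sequence, gene, tss, is_nontargeting``; one row per
        sgRNA; protospacer sequences are uppercase ACGT of uniform length.
    """

    table: pd.DataFrame

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SgRNALibrary":
        """Validate a raw frame and return a library.

        Enforces: unique ids, unique sequences (duplicates reported with the
        offending ids), ACGT-only uppercase sequences of uniform length,
        sentinel gene/tss on non-targeting rows, and at least one
        non-targeting record.
        """
        missing = [c for c in LIBRARY_COLUMNS if c not in frame.columns]
        if missing:
            raise LibraryError(f"library table missing columns: {missing}")
        tab = frame.loc[:, LIBRARY_COLUMNS].copy()
        tab["sgrna_id"] = tab["sgrna_id"].astype(str)
        tab["sequence"] = tab["sequence"].astype(str).str.upper()
        tab["gene"] = tab["gene"].astype(str)
        tab["tss"] = tab["tss"].astype(str)
        tab["is_nontargeting"] = tab["is_nontargeting"].astype(bool)

        if tab.empty:
            raise LibraryError("library is empty")

        dup_ids = tab.loc[tab["sgrna_id"].duplicated(keep=False), "sgrna_id"]
        if not dup_ids.empty:
            raise LibraryError(f"duplicate sgrna_id: {sorted(dup_ids.unique())}")
        dup_seq = tab.loc[tab["sequence"].duplicated(keep=False)]
        if not dup_seq.empty:
            groups = dup_seq.groupby("sequence")["sgrna_id"].apply(list).to_dict()
            raise LibraryError(f"duplicate sequences shared by: {groups}")

        bad = tab.loc[~tab["sequence"].map(lambda s: set(s) <= _VALID_BASES)]
        if not bad.empty:
            raise LibraryError(
                f"non-ACGT characters in sequences of: {bad['sgrna_id'].tolist()}"
            )
        lengths = tab["sequence"].str.len()
        if lengths.nunique() != 1:
            ragged = tab.loc[lengths != lengths.mode()[0], "sgrna_id"].tolist()
            raise LibraryError(f"ragged protospacer lengths; offending ids: {ragged}")

        nt = tab["is_nontargeting"]
        if not nt.any():
            raise LibraryError(
                "library has no non-targeting sgRNAs; at least one is required "
                "for phenotype normalization"
            )
        tab.loc[nt, "gene"] = NONTARGETING_GENE
        tab.loc[nt, "tss"] = NONTARGETING_TSS
        tab = tab.reset_index(drop=True)
        return cls(tab)

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sgrna_ids(self) -> pd.Index:
        return pd.Index(self.table["sgrna_id"])

    @property
    def protospacer_length(self) -> int:
        return len(self.table["sequence"].iat[0])

    @property
    def nontargeting_ids(self) -> list[str]:
        nt = self.table["is_nontargeting"]
        return self.table.loc[nt, "sgrna_id"].tolist()

    @property
    def targeting(self) -> pd.DataFrame:
        return self.table.loc[~self.table["is_nontargeting"]]

    def sequence_index(self) -> dict[str, str]:
        """Mapping protospacer sequence -> sgrna_id (sequences are unique)."""
        return dict(zip(self.table["sequence"], self.table["sgrna_id"]))

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["is_nontargeting"] = out["is_nontargeting"].astype(int)
        out.to_csv(path, index=False)

    def to_fasta(self, path: str | Path) -> None:
        """Write FASTA with headers ``id|gene|tss`` (``|NT`` appended for
        non-targeting records)."""
        records = []
        for row in self.table.itertuples(index=False):
            header = f"{row.sgrna_id}|{row.gene}|{row.tss}"
            if row.is_nontargeting:
                header += "|NT"
            records.append(SeqRecord(Seq(row.sequence), id=header, description=""))
        SeqIO.write(records, str(path), "fasta")


def load_library(path: str | Path, fmt: str | None = None) -> SgRNALibrary:
    """Load a library from CSV or FASTA (format inferred from suffix if not given)."""
    path = Path(path)
    if fmt is None:
        fmt = "fasta" if path.suffix.lower() in {".fa", ".fasta", ".fna"} else "csv"
    if fmt == "csv":
        frame = pd.read_csv(path, dtype={"sgrna_id": str, "gene": str, "tss": str})
        return SgRNALibrary.from_frame(frame)
    if fmt == "fasta":
        rows = []
        for rec in SeqIO.parse(str(path), "fasta"):
            fields = rec.id.split("|")
            if len(fields) not in (3, 4):
                raise LibraryError(
                    f"FASTA header {rec.id!r}: expected 'id|gene|tss' or 'id|gene|tss|NT'"
                )
            rows.append(
                {
                    "sgrna_id": fields[0],
                    "sequence": str(rec.seq),
                    "gene": fields[1],
                    "tss": fields[2],
                    "is_nontargeting": len(fields) == 4 and fields[3] == "NT",
                }
            )
        return SgRNALibrary.from_frame(pd.DataFrame(rows))
    raise ValueError(f"unknown library format {fmt!r}")
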