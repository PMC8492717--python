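"""Aligned FASTA I/O, haplotype collapsing and window extraction.

Coordinates are 0-based half-open internally; CLI layers present
1-based inclusive coordinates.  Bases other than A/C/G/T (gaps, N and
all IUPAC ambiguity codes) are treated as missing data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset(b"ACGT")
_VALID_ARR = np.frombuffer(b"ACGT", dtype="S1")

MissingPolicy = Literal["exclude_site", "pairwise"]
PopLevel = Literal["breed", "region", "metapopulation"]


class AlignmentError(ValueError):
    """Raised for malformed alignments (unequal lengths, empty input...)."""


class MetadataError(ValueError):
    """Raised when sample metadata does not match the FASTA records."""


@dataclass(frozen=True)
class SampleLabel:
    breed: str = ""
    region: str = ""
    metapopulation: str = ""

    def level(self, pop_level: PopLevel) -> str:
        return getattr(self, pop_level)


@dataclass
class Alignment:
    """Aligned sequences with per-sample population labels.

    ``seqs`` is an (n_samples, L) byte matrix over ``{A,C,G,T,-,N,...}``;
    rows are parallel to ``sample_ids``.
    """

    sample_ids: list[str]
    seqs: np.ndarray
    labels: dict[str, SampleLabel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs, dtype="S1")
        if self.seqs.ndim != 2:
            raise AlignmentError("sequence matrix must be 2-D")
        if len(self.sample_ids) != self.seqs.shape[0]:
            raise AlignmentError(
                f"{len(self.sample_ids)} ids but {self.seqs.shape[0]} sequences"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AlignmentError("sample ids are not unique")
        for sid in self.sample_ids:
            self.labels.setdefault(sid, SampleLabel())

    @property
    def n(self) -> int:
        return self.seqs.shape[0]

    @property
    def L(self) -> int:
        return self.seqs.shape[1]

    def populations(self, pop_level: PopLevel = "breed") -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for sid in self.sample_ids:
            seen.setdefault(self.labels[sid].level(pop_level), None)
        return list(seen)

    def pop_labels(self, pop_level: PopLevel = "breed") -> list[str]:
        """Per-sample population label, parallel to ``sample_ids``."""
        return [self.labels[sid].level(pop_level) for sid in self.sample_ids]

    def subset(self, sample_ids: Sequence[str]) -> "Alignment":
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        try:
            rows = [index[sid] for sid in sample_ids]
        except KeyError as exc:
            raise MetadataError(f"unknown sample id {exc.args[0]!r}") from None
        return Alignment(
            list(sample_ids),
            self.seqs[rows],
            {sid: self.labels[sid] for sid in sample_ids},
        )

    def restrict_to_population(
        self, pop: str, pop_level: PopLevel = "breed"
    ) -> "Alignment":
        keep = [
            sid
            for sid in self.sample_ids
            if self.labels[sid].level(pop_level) == pop
        ]
        if not keep:
            raise MetadataError(f"no samples with {pop_level}={pop!r}")
        return self.subset(keep)

    def valid_mask(self) -> np.ndarray:
        """Boolean (n, L) matrix, True where the base is unambiguous A/C/G/T."""
        return np.isin(self.seqs, _VALID_ARR)

    def retained_sites(self, missing_policy: MissingPolicy) -> np.ndarray:
        """Columns kept under the missing-data policy (0-based indices)."""
        if missing_policy == "exclude_site":
            return np.flatnonzero(self.valid_mask().all(axis=0))
        if missing_policy == "pairwise":
            return np.arange(self.L)
        raise ValueError(f"unknown missing policy {missing_policy!r}")

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(row.tobytes().decode("ascii")), id=sid, description="")
            for sid, row in zip(self.sample_ids, self.seqs)
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_metadata(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["sample_id", "breed", "region", "metapopulation"])
            for sid in self.sample_ids:
                lab = self.labels[sid]
                writer.writerow([sid, lab.breed, lab.region, lab.metapopulation])


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with per-population counts.

    ``haplotypes[i]`` is the character string of haplotype ``i`` over
    ``retained_sites``; ``counts`` is (n_haplotypes, n_populations).
    """

    haplotypes: list[str]
    populations: list[str]
    counts: np.ndarray
    assignment: dict[str, int]
    retained_sites: np.ndarray

    @property
    def k(self) -> int:
        return len(self.haplotypes)

    def total_counts(self) -> np.ndarray:
        """Carrier count per haplotype across all populations."""
        return self.counts.sum(axis=1)

    def singleton_count(self) -> int:
        return int((self.total_counts() == 1).sum())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["haplotype_id", "sequence", *self.populations, "total"])
            totals = self.total_counts()
            for i, hap in enumerate(self.haplotypes):
                writer.writerow(
                    [f"H{i + 1}", hap, *map(int, self.counts[i]), int(totals[i])]
                )


def _seq_matrix(records: list[SeqRecord]) -> np.ndarray:
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise AlignmentError(
            f"records have unequal lengths {sorted(lengths)}; input must be aligned"
        )
    buf = b"".join(str(r.seq).upper().encode("ascii") for r in records)
    return np.frombuffer(buf, dtype="S1").reshape(len(records), lengths.pop())


def read_metadata(path: str | Path) -> dict[str, SampleLabel]:
    labels: dict[str, SampleLabel] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "breed", "region", "metapopulation"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise MetadataError(
                f"metadata must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            sid = row["sample_id"]
            if sid in labels:
                raise MetadataError(f"duplicate metadata row for {sid!r}")
            labels[sid] = SampleLabel(
                row["breed"] or "", row["region"] or "", row["metapopulation"] or ""
            )
    return labels


def read_alignment(fasta_path: str | Path, metadata_path: str | Path) -> Alignment:
    """Read an aligned FASTA and join sample metadata.

    Record order is preserved; sequences are uppercased.  Every FASTA id
    must have a metadata row.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    labels = read_metadata(metadata_path)
    ids = [r.id for r in records]
    missing = [sid for sid in ids if sid not in labels]
    if missing:
        raise MetadataError(
            f"{len(missing)} FASTA ids missing from metadata, first: {missing[0]!r}"
        )
    return Alignment(ids, _seq_matrix(records), {sid: labels[sid] for sid in ids})


def polymorphic_sites(
    a: Alignment, missing_policy: MissingPolicy = "exclude_site"
) -> list[int]:
    """0-based columns with >= 2 distinct unambiguous bases.

    Under ``exclude_site``, columns containing any missing/ambiguous
    character are dropped before scanning.
    """
    if a.n == 0:
        raise AlignmentError("empty alignment")
    valid = a.valid_mask()
    sites = a.retained_sites(missing_policy)
    out: list[int] = []
    for j in sites:
        col = a.seqs[:, j][valid[:, j]]
        if len(np.unique(col)) >= 2:
            out.append(int(j))
    return out


def collapse_haplotypes(
    a: Alignment,
    missing_policy: MissingPolicy = "exclude_site",
    pop_level: PopLevel = "breed",
) -> HaplotypeTable:
    """Group samples identical over the retained sites into haplotypes."""
    if a.n == 0:
        raise AlignmentError("empty alignment")
    sites = a.retained_sites(missing_policy)
    if sites.size == 0:
        raise AlignmentError(
            "missing-data policy removed every site; "
            "check gap/N content or use missing_policy='pairwise'"
        )
    sub = a.seqs[:, sites]
    pops = a.populations(pop_level)
    pop_index = {p: j for j, p in enumerate(pops)}

    hap_index: dict[bytes, int] = {}
    haplotypes: list[str] = []
    assignment: dict[str, int] = {}
    counts_rows: list[np.ndarray] = []
    for i, sid in enumerate(a.sample_ids):
        key = sub[i].tobytes()
        h = hap_index.get(key)
        if h is None:
            h = len(haplotypes)
            hap_index[key] = h
            haplotypes.append(key.decode("ascii"))
            counts_rows.append(np.zeros(len(pops), dtype=np.int64))
        assignment[sid] = h
        counts_rows[h][pop_index[a.labels[sid].level(pop_level)]] += 1
    return HaplotypeTable(
        haplotypes, pops, np.vstack(counts_rows), assignment, sites
    )


def extract_window(a: Alignment, start: int, end: int) -> Alignment:
    """Slice columns [start, end) into a new alignment; labels preserved."""
    if not (0 <= start < end <= a.L):
        raise AlignmentError(
            f"window [{start}, {end}) out of range for alignment of length {a.L}"
        )
    return Alignment(list(a.sample_ids), a.seqs[:, start:end].copy(), dict(a.labels))


def from_strings(
    seqs: Iterable[str],
    sample_ids: Sequence[str] | None = None,
    labels: Mapping[str, SampleLabel | tuple[str, ...]] | None = None,
    pops: Sequence[str] | None = None,
) -> Alignment:
    """Convenience constructor from python strings (used by tests/fixtures).

    ``pops`` assigns breed labels positionally when given.
    """
    seq_list = [s.upper() for s in seqs]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(len(seq_list))]
    lab: dict[str, SampleLabel] = {}
    if labels:
        for sid, val in labels.items():
            lab[sid] = val if isinstance(val, SampleLabel) else SampleLabel(*val)
    if pops is not None:
        if len(pops) != len(seq_list):
            raise MetadataError("pops must be parallel to seqs")
        for sid, p in zip(sample_ids, pops):
            lab[sid] = SampleLabel(breed=p)
    lengths = {len(s) for s in seq_list}
    if len(lengths) > 1:
        raise AlignmentError(f"unequal sequence lengths {sorted(lengths)}")
    mat = np.frombuffer(
        "".join(seq_list).encode("ascii"), dtype="S1"
    ).reshape(len(seq_list), lengths.pop() if lengths else 0)
    return Alignment(list(sample_ids), mat.copy(), lab)
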