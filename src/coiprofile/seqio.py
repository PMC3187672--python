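"""Alignment and taxonomy I/O, window trimming, and translation screening.

All coordinates are 0-based, half-open.  Sequences are normalized to upper
case on input; gaps ('-'), N and IUPAC ambiguity codes are preserved and
handled downstream at distance time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data import CodonTable

NUCLEOTIDE_ALPHABET = frozenset("ACGTUNRYSWKMBDHV-")
UNAMBIGUOUS = frozenset("ACGT")

#: NCBI translation table 5 (invertebrate mitochondrial) is the default
#: genetic code for the translation screen.
DEFAULT_GENETIC_CODE = 5


class AlignmentError(ValueError):
    """Raised when an alignment violates a structural invariant."""


class TaxonomyError(ValueError):
    """Raised when a taxonomy table is malformed or incomplete."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned specimen sequence."""

    specimen_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise AlignmentError("empty specimen id")
        if not self.sequence:
            raise AlignmentError(f"empty sequence for {self.specimen_id!r}")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        for pos, ch in enumerate(seq):
            if ch not in NUCLEOTIDE_ALPHABET:
                raise AlignmentError(
                    f"illegal character {ch!r} at position {pos} in "
                    f"{self.specimen_id!r}"
                )


class AlignedSeqSet:
    """An ordered set of equal-length sequences keyed by specimen id."""

    def __init__(self, records: Iterable[SequenceRecord]):
        records = list(records)
        if len(records) < 2:
            raise AlignmentError("an alignment needs at least 2 sequences")
        seen: set[str] = set()
        for rec in records:
            if rec.specimen_id in seen:
                raise AlignmentError(f"duplicate id {rec.specimen_id!r}")
            seen.add(rec.specimen_id)
        length = len(records[0].sequence)
        bad = [r.specimen_id for r in records if len(r.sequence) != length]
        if bad:
            raise AlignmentError(
                "unequal lengths: " + ", ".join(repr(b) for b in bad)
            )
        self._records = records
        self._index = {r.specimen_id: r for r in records}
        self.length = length

    @property
    def ids(self) -> list[str]:
        return [r.specimen_id for r in self._records]

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self._records)

    def __getitem__(self, specimen_id: str) -> SequenceRecord:
        return self._index[specimen_id]

    def __contains__(self, specimen_id: str) -> bool:
        return specimen_id in self._index

    def subset(self, ids: Iterable[str]) -> "AlignedSeqSet":
        return AlignedSeqSet(self._index[i] for i in ids)


@dataclass(frozen=True)
class TaxonInfo:
    species: str
    group: str
    ingroup: bool


class TaxonMap:
    """specimen id -> (species, genus/subgenus/species-group, ingroup flag)."""

    def __init__(self, entries: dict[str, TaxonInfo]):
        for sid, info in entries.items():
            if not sid:
                raise TaxonomyError("empty specimen id")
            if not info.species:
                raise TaxonomyError(f"blank species for {sid!r}")
            if not info.group:
                raise TaxonomyError(f"blank group for {sid!r}")
        self._entries = dict(entries)

    def __getitem__(self, specimen_id: str) -> TaxonInfo:
        return self._entries[specimen_id]

    def __contains__(self, specimen_id: str) -> bool:
        return specimen_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def specimen_ids(self) -> list[str]:
        return list(self._entries)

    def species_of(self, specimen_id: str) -> str:
        return self._entries[specimen_id].species

    def group_of(self, specimen_id: str) -> str:
        return self._entries[specimen_id].group

    def is_ingroup(self, specimen_id: str) -> bool:
        return self._entries[specimen_id].ingroup

    def species_members(
        self, ids: Iterable[str] | None = None, ingroup_only: bool = False
    ) -> dict[str, list[str]]:
        """Map species -> specimen ids, restricted to ``ids`` if given."""
        pool = list(ids) if ids is not None else self.specimen_ids
        out: dict[str, list[str]] = {}
        for sid in pool:
            info = self._entries[sid]
            if ingroup_only and not info.ingroup:
                continue
            out.setdefault(info.species, []).append(sid)
        return out

    def group_species(
        self, ids: Iterable[str] | None = None, ingroup_only: bool = False
    ) -> dict[str, dict[str, list[str]]]:
        """Map group -> species -> specimen ids."""
        out: dict[str, dict[str, list[str]]] = {}
        for sp, members in self.species_members(ids, ingroup_only).items():
            grp = self._entries[members[0]].group
            out.setdefault(grp, {})[sp] = members
        return out

    def check_covers(self, aln: AlignedSeqSet) -> None:
        missing = [i for i in aln.ids if i not in self._entries]
        if missing:
            raise TaxonomyError(
                "specimens missing from taxonomy: "
                + ", ".join(repr(m) for m in missing)
            )


def read_fasta(path: str | Path) -> AlignedSeqSet:
    """Read an aligned FASTA file into an :class:`AlignedSeqSet`.

    Record order is preserved; sequences are upper-cased.  Raises
    :class:`AlignmentError` on unequal lengths, duplicate ids, or illegal
    characters.
    """
    records = [
        SequenceRecord(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return AlignedSeqSet(records)


def write_fasta(aln: AlignedSeqSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in aln:
            fh.write(f">{rec.specimen_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_TRUE = {"true", "t", "yes", "y", "1"}
_FALSE = {"false", "f", "no", "n", "0"}


def _parse_bool(text: str, context: str) -> bool:
    low = text.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise TaxonomyError(f"cannot parse ingroup value {text!r} for {context}")


def read_taxonomy(path: str | Path) -> TaxonMap:
    """Read a delimited taxonomy table (TSV or CSV, sniffed from header).

    Required columns: specimen_id, species, group, ingroup.
    """
    with open(path, newline="") as fh:
        head = fh.readline()
        if not head:
            raise TaxonomyError("empty taxonomy file")
        delim = "\t" if "\t" in head else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        required = {"specimen_id", "species", "group", "ingroup"}
        fields = {f.strip() for f in reader.fieldnames or []}
        missing = required - fields
        if missing:
            raise TaxonomyError(
                "missing column(s): " + ", ".join(sorted(missing))
            )
        entries: dict[str, TaxonInfo] = {}
        for row in reader:
            sid = (row["specimen_id"] or "").strip()
            if not sid:
                raise TaxonomyError("row with empty specimen_id")
            if sid in entries:
                raise TaxonomyError(f"duplicate specimen_id {sid!r}")
            species = (row["species"] or "").strip()
            group = (row["group"] or "").strip()
            if not species:
                raise TaxonomyError(f"blank species for {sid!r}")
            entries[sid] = TaxonInfo(
                species=species,
                group=group,
                ingroup=_parse_bool(row["ingroup"] or "", sid),
            )
    return TaxonMap(entries)


def write_taxonomy(tax: TaxonMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["specimen_id", "species", "group", "ingroup"])
        for sid in tax.specimen_ids:
            info = tax[sid]
            writer.writerow(
                [sid, info.species, info.group, str(info.ingroup).lower()]
            )


def trim_window(aln: AlignedSeqSet, start: int, end: int) -> AlignedSeqSet:
    """Slice every sequence to columns [start, end) (0-based, half-open)."""
    if not (0 <= start < end <= aln.length):
        raise AlignmentError(
            f"window [{start}, {end}) out of range for length {aln.length}"
        )
    return AlignedSeqSet(
        SequenceRecord(r.specimen_id, r.sequence[start:end]) for r in aln
    )


@dataclass(frozen=True)
class TranslationResult:
    specimen_id: str
    frame: int
    passed: bool
    n_internal_stops: int
    n_codons: int


def _codon_stops(seq: str, frame: int, stop_codons: frozenset[str]) -> tuple[int, int]:
    """Count internal stop codons of ``seq`` read in ``frame``.

    Codons containing a gap or ambiguous base are skipped whole.  A stop in
    the final complete codon position is terminal, not internal.
    """
    codons = [
        seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)
    ]
    n_stops = 0
    n_judged = 0
    last = len(codons) - 1
    for idx, codon in enumerate(codons):
        if any(ch not in UNAMBIGUOUS for ch in codon):
            continue
        n_judged += 1
        if codon in stop_codons and idx != last:
            n_stops += 1
    return n_stops, n_judged


def translation_screen(
    aln: AlignedSeqSet,
    code: int = DEFAULT_GENETIC_CODE,
    frame: int | str = "auto",
) -> list[TranslationResult]:
    """Screen each sequence for protein-coding integrity.

    A sequence passes iff its translation in the chosen frame contains no
    internal stop codon.  ``frame='auto'`` picks, for the whole set, the
    frame minimizing the total number of internal stops.
    """
    table = CodonTable.unambiguous_dna_by_id[code]
    stops = frozenset(table.stop_codons)
    if frame == "auto":
        totals = []
        for f in (0, 1, 2):
            totals.append(
                sum(_codon_stops(r.sequence, f, stops)[0] for r in aln)
            )
        chosen = min(range(3), key=lambda f: totals[f])
    else:
        chosen = int(frame)
        if chosen not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1, 2 or 'auto', got {frame!r}")
    results = []
    for rec in aln:
        n_stops, n_judged = _codon_stops(rec.sequence, chosen, stops)
        results.append(
            TranslationResult(
                specimen_id=rec.specimen_id,
                frame=chosen,
                passed=n_stops == 0,
                n_internal_stops=n_stops,
                n_codons=n_judged,
            )
        )
    return results
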