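"""Peptide library definitions, read counting, and tabular I/O.

A screened library is a defined set of fixed-length peptides: wild-type
tyrosine phosphosites, point variants, saturation-mutagenesis scan
variants, and tyrosine-free negative controls (peptides that cannot be
phosphorylated, used to calibrate the non-specific background of a
selection). Sequencing reads are counted against the library by slicing
the peptide-coding region out of each read, translating it in frame, and
requiring an exact amino-acid match, so synonymous codons collapse onto
the same peptide.

All tabular artifacts are tab-separated text with ``#``-prefixed metadata
lines and round-trip losslessly through the matching reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "AMINO_ACIDS",
    "CATEGORIES",
    "ValidationError",
    "ComputationError",
    "PeptideEntry",
    "PeptideLibrary",
    "ReadLayout",
    "CountTable",
    "read_library",
    "write_library",
    "count_reads",
    "write_table",
    "read_count_table",
]

#: The 20 canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Allowed peptide categories.
CATEGORIES = frozenset(
    {"wildtype_site", "variant", "tyr_free_control", "scan_variant"}
)

_DNA_BASES = frozenset("ACGT")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class ComputationError(RuntimeError):
    """Raised when a computation cannot proceed (e.g. failed fit setup)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeptideEntry:
    """One library member.

    Parameters
    ----------
    id
        Unique text label.
    peptide
        Amino-acid sequence, single-letter uppercase, canonical alphabet.
    category
        One of :data:`CATEGORIES`.
    phospho_index
        0-based offset of the phosphotyrosine within ``peptide``; absent
        for tyrosine-free controls.
    site_label
        Optional free-text provenance, e.g. ``"PD-1 pTyr223"``.
    coding_dna
        Optional nucleotide sequence whose translation must equal
        ``peptide``.
    """

    id: str
    peptide: str
    category: str
    phospho_index: int | None = None
    site_label: str | None = None
    coding_dna: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("peptide entry requires a non-empty id")
        bad = set(self.peptide) - set(AMINO_ACIDS)
        if bad:
            raise ValidationError(
                f"peptide {self.id!r} contains non-canonical letters "
                f"{sorted(bad)}"
            )
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"peptide {self.id!r}: unknown category {self.category!r}"
            )
        n_tyr = self.peptide.count("Y")
        if self.category == "tyr_free_control" and n_tyr > 0:
            raise ValidationError(
                f"tyr_free_control {self.id!r} contains a tyrosine"
            )
        if self.category != "tyr_free_control" and n_tyr == 0:
            raise ValidationError(
                f"peptide {self.id!r} has no tyrosine but is categorised "
                f"as {self.category!r}"
            )
        if self.phospho_index is not None:
            if not 0 <= self.phospho_index < len(self.peptide):
                raise ValidationError(
                    f"peptide {self.id!r}: phospho_index out of range"
                )
            if self.peptide[self.phospho_index] != "Y":
                raise ValidationError(
                    f"peptide {self.id!r}: residue at phospho_index is not Y"
                )
        if self.coding_dna is not None:
            translated = str(Seq(self.coding_dna).translate())
            if translated != self.peptide:
                raise ValidationError(
                    f"peptide {self.id!r}: coding_dna translates to "
                    f"{translated!r}, not {self.peptide!r}"
                )

    @property
    def n_tyrosines(self) -> int:
        return self.peptide.count("Y")


@dataclass(frozen=True)
class PeptideLibrary:
    """A named, validated collection of fixed-length peptides."""

    name: str
    entries: tuple[PeptideEntry, ...]
    peptide_length: int
    require_controls: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate peptide ids: {dupes}")
        for e in self.entries:
            if len(e.peptide) != self.peptide_length:
                raise ValidationError(
                    f"peptide {e.id!r} has length {len(e.peptide)}, "
                    f"library requires {self.peptide_length}"
                )
        if self.require_controls and not any(
            e.category == "tyr_free_control" for e in self.entries
        ):
            raise ValidationError(
                "library must contain at least one tyr_free_control entry "
                "for background calibration"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, peptide_id: str) -> PeptideEntry:
        return self._by_id[peptide_id]

    def __contains__(self, peptide_id: str) -> bool:
        return peptide_id in self._by_id

    @property
    def _by_id(self) -> dict[str, PeptideEntry]:
        return {e.id: e for e in self.entries}

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def by_peptide(self) -> dict[str, str]:
        """Map peptide sequence -> id (first occurrence wins)."""
        out: dict[str, str] = {}
        for e in self.entries:
            out.setdefault(e.peptide, e.id)
        return out

    def control_ids(self) -> list[str]:
        return [e.id for e in self.entries if e.category == "tyr_free_control"]

    def single_tyrosine_ids(self) -> list[str]:
        """Ids of non-control peptides with exactly one tyrosine."""
        return [
            e.id
            for e in self.entries
            if e.category != "tyr_free_control" and e.n_tyrosines == 1
        ]


@dataclass(frozen=True)
class ReadLayout:
    """Position of the peptide-coding region inside each sequencing read.

    ``offset`` is the 0-based start of the coding region; ``length`` its
    length in nucleotides, or ``None`` for "rest of the read". The default
    layout is the whole read in frame 0.
    """

    offset: int = 0
    length: int | None = None

    def slice(self, read: str) -> str:
        end = len(read) if self.length is None else self.offset + self.length
        if self.offset < 0 or end > len(read):
            raise ValidationError(
                f"coding region [{self.offset}:{end}] extends past read "
                f"end (read length {len(read)})"
            )
        return read[self.offset : end]


@dataclass
class CountTable:
    """Per-peptide read counts for one sample of one library."""

    library_name: str
    sample_label: str
    counts: dict[str, int]
    total_matched: int
    total_reads: int
    discarded: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError("counts must be non-negative")
        if sum(self.counts.values()) != self.total_matched:
            raise ValidationError("sum of counts must equal total_matched")
        if self.total_matched + sum(self.discarded.values()) != self.total_reads:
            raise ValidationError(
                "total_reads must equal total_matched + discarded reads"
            )

    def as_series(self) -> pd.Series:
        s = pd.Series(self.counts, dtype="int64")
        s.index.name = "id"
        s.name = self.sample_label
        return s


# ---------------------------------------------------------------------------
# Library reading / writing
# ---------------------------------------------------------------------------

_LIB_COLUMNS = ("id", "peptide", "category")
_OPT_COLUMNS = ("phospho_index", "site_label", "coding_dna")


def read_library(path: str | Path, name: str | None = None,
                 require_controls: bool = True) -> PeptideLibrary:
    """Load and validate a peptide library from a TSV file.

    The file must have columns ``id``, ``peptide``, ``category``;
    ``phospho_index``, ``site_label`` and ``coding_dna`` are optional.
    ``phospho_index`` is auto-filled as the index of the unique tyrosine
    when a peptide contains exactly one.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _LIB_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"library file missing columns: {missing}")
    entries = []
    for row in df.itertuples(index=False):
        peptide = str(row.peptide)
        phospho_index: int | None = None
        if "phospho_index" in df.columns and pd.notna(row.phospho_index):
            phospho_index = int(float(row.phospho_index))
        elif peptide.count("Y") == 1:
            phospho_index = peptide.index("Y")
        entries.append(
            PeptideEntry(
                id=str(row.id),
                peptide=peptide,
                category=str(row.category),
                phospho_index=phospho_index,
                site_label=(
                    str(row.site_label)
                    if "site_label" in df.columns and pd.notna(row.site_label)
                    else None
                ),
                coding_dna=(
                    str(row.coding_dna)
                    if "coding_dna" in df.columns and pd.notna(row.coding_dna)
                    else None
                ),
            )
        )
    if not entries:
        raise ValidationError(f"library file {path} contains no entries")
    length = len(entries[0].peptide)
    return PeptideLibrary(
        name=name or path.stem,
        entries=tuple(entries),
        peptide_length=length,
        require_controls=require_controls,
    )


def write_library(lib: PeptideLibrary, path: str | Path) -> None:
    rows = [
        {
            "id": e.id,
            "peptide": e.peptide,
            "category": e.category,
            "phospho_index": e.phospho_index,
            "site_label": e.site_label,
            "coding_dna": e.coding_dna,
        }
        for e in lib.entries
    ]
    df = pd.DataFrame(rows)
    _write_tsv(df, path, {"type": "PeptideLibrary", "library_name": lib.name,
                          "peptide_length": lib.peptide_length})


# ---------------------------------------------------------------------------
# Read counting
# ---------------------------------------------------------------------------


def count_reads(
    fastq: str | Path | Iterable[str],
    lib: PeptideLibrary,
    layout: ReadLayout | None = None,
    sample_label: str = "sample",
) -> CountTable:
    """Count FASTQ reads against a library by exact translated match.

    Each read is sliced at the coding region given by ``layout``,
    translated in frame, and counted iff the translated peptide exactly
    matches a library peptide. Reads containing ambiguous bases or stop
    codons in the coding region, reads whose coding region is not a whole
    number of codons, and reads with no exact match are tallied under
    ``discarded`` with reasons. Phred qualities are ignored.
    """
    layout = layout or ReadLayout()
    by_peptide = lib.by_peptide()
    counts = {pid: 0 for pid in lib.ids}
    discarded: dict[str, int] = {}
    total_reads = 0

    def _discard(reason: str) -> None:
        discarded[reason] = discarded.get(reason, 0) + 1

    if isinstance(fastq, (str, Path)):
        reads = (str(rec.seq) for rec in SeqIO.parse(str(fastq), "fastq"))
    else:
        reads = iter(fastq)

    for read in reads:
        total_reads += 1
        region = layout.slice(read.upper())
        if len(region) % 3 != 0:
            _discard("partial_codon")
            continue
        if set(region) - _DNA_BASES:
            _discard("ambiguous_base")
            continue
        peptide = str(Seq(region).translate())
        if "*" in peptide:
            _discard("stop_codon")
            continue
        pid = by_peptide.get(peptide)
        if pid is None:
            _discard("no_match")
            continue
        counts[pid] += 1

    total_matched = sum(counts.values())
    return CountTable(
        library_name=lib.name,
        sample_label=sample_label,
        counts=counts,
        total_matched=total_matched,
        total_reads=total_reads,
        discarded=discarded,
    )


# ---------------------------------------------------------------------------
# Generic tabular I/O
# ---------------------------------------------------------------------------


def _meta_lines(meta: Mapping[str, object]) -> str:
    from . import __version__

    lines = [f"# sh2screen_version: {__version__}"]
    for key, value in meta.items():
        if isinstance(value, (dict, list)):
            value = json.dumps(value, sort_keys=True)
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


def _write_tsv(df: pd.DataFrame, path: str | Path,
               meta: Mapping[str, object]) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(meta))
        df.to_csv(fh, sep="\t", index=False)


def _read_meta(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ": " in body:
                key, value = body.split(": ", 1)
                meta[key] = value
    return meta


def write_table(obj, path: str | Path) -> None:
    """Write any tabular result defined by this package to TSV.

    Dispatches on type; every writer has a matching reader that
    round-trips the object losslessly.
    """
    # local imports: enrichment/specificity depend on this module
    from .enrichment import EnrichmentTable, FrequencyTable
    from .specificity import HitSet, LogoMatrix, ScanMatrix

    if isinstance(obj, CountTable):
        df = pd.DataFrame(
            {"id": list(obj.counts), "count": list(obj.counts.values())}
        )
        _write_tsv(df, path, {
            "type": "CountTable",
            "library_name": obj.library_name,
            "sample_label": obj.sample_label,
            "total_matched": obj.total_matched,
            "total_reads": obj.total_reads,
            "discarded": obj.discarded,
        })
    elif isinstance(obj, PeptideLibrary):
        write_library(obj, path)
    elif isinstance(obj, FrequencyTable):
        df = obj.freqs.rename("frequency").rename_axis("id").reset_index()
        _write_tsv(df, path, {
            "type": "FrequencyTable",
            "library_name": obj.library_name,
            "sample_label": obj.sample_label,
            "pseudocount": obj.pseudocount,
        })
    elif isinstance(obj, EnrichmentTable):
        df = obj.scores.copy()
        df["mean"] = obj.mean
        df = df.rename_axis("id").reset_index()
        _write_tsv(df, path, {
            "type": "EnrichmentTable",
            "domain_label": obj.domain_label,
            "replicates": list(obj.scores.columns),
            "source_libraries": obj.source_libraries,
        })
    elif isinstance(obj, HitSet):
        df = pd.DataFrame({"id": sorted(obj.hit_ids)})
        _write_tsv(df, path, {
            "type": "HitSet",
            "domain_label": obj.domain_label,
            "cutoff": obj.cutoff,
            "control_fpr_at_cutoff": obj.control_fpr_at_cutoff,
        })
    elif isinstance(obj, (LogoMatrix, ScanMatrix)):
        df = obj.values.rename_axis("position").reset_index()
        meta: dict[str, object] = {"type": type(obj).__name__}
        if isinstance(obj, LogoMatrix):
            meta.update(pseudocount=obj.pseudocount,
                        n_enriched=obj.n_enriched, n_library=obj.n_library)
        else:
            meta.update(wt_peptide=obj.wt_peptide)
        _write_tsv(df, path, meta)
    else:
        raise ValidationError(
            f"write_table does not know how to serialise {type(obj).__name__}"
        )


def read_count_table(path: str | Path) -> CountTable:
    meta = _read_meta(path)
    if meta.get("type") != "CountTable":
        raise ValidationError(f"{path} is not a CountTable file")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    counts = (
        dict(zip(df["id"], df["count"].astype(int))) if len(df) else {}
    )
    return CountTable(
        library_name=meta["library_name"],
        sample_label=meta["sample_label"],
        counts=counts,
        total_matched=int(meta["total_matched"]),
        total_reads=int(meta["total_reads"]),
        discarded={k: int(v) for k, v in json.loads(meta["discarded"]).items()},
    )
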