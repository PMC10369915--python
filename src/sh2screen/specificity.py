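"""Hit calling, overlaps, sequence logos, and scanning-mutagenesis matrices.

Tyrosine-free control peptides cannot be phosphorylated, so their
enrichment scores sample the non-specific background of the bead
selection. The hit cutoff is either fixed by the user or calibrated as
the smallest score above which at most a chosen fraction of controls
fall. Hits are single-tyrosine, non-control peptides whose mean score
strictly exceeds the cutoff.

Position-specific preferences are summarised two ways: a log-odds logo
comparing the amino-acid composition of the hit set to the full
single-tyrosine library at each position relative to the phosphotyrosine
(pTyr = 0, excluded), and a scanning-mutagenesis matrix of
log2(variant score / wild-type score) for a saturation library built
around one site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import EnrichmentTable
from .library_io import AMINO_ACIDS, PeptideLibrary, ValidationError

__all__ = [
    "HitSet",
    "OverlapReport",
    "LogoMatrix",
    "ScanMatrix",
    "DomainComparison",
    "calibrate_cutoff",
    "call_hits",
    "hit_overlap",
    "logo_matrix",
    "scan_matrix",
    "compare_domains",
]


@dataclass(frozen=True)
class HitSet:
    """Peptides called as true binders at a given cutoff."""

    domain_label: str
    cutoff: float
    hit_ids: frozenset[str]
    control_fpr_at_cutoff: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "hit_ids", frozenset(self.hit_ids))
        if not 0.0 <= self.control_fpr_at_cutoff <= 1.0:
            raise ValidationError("control FPR must be in [0, 1]")

    def __len__(self) -> int:
        return len(self.hit_ids)


@dataclass(frozen=True)
class OverlapReport:
    """Exact Venn decomposition of several hit sets.

    ``region_counts`` maps a tuple of set labels to the number of
    elements that belong to exactly those sets and no others.
    """

    labels: tuple[str, ...]
    region_counts: dict[tuple[str, ...], int]
    union_size: int

    def count(self, *labels: str) -> int:
        return self.region_counts.get(tuple(sorted(labels)), 0)


@dataclass
class LogoMatrix:
    """Per-position log2 enrichment of each amino acid in a hit set.

    ``values`` rows are positions relative to the phosphotyrosine
    (pTyr = 0 excluded), columns the 20 amino acids; each cell is
    log2(f_enriched / f_library) under a shared pseudocount scheme.
    """

    values: pd.DataFrame
    pseudocount: float
    n_enriched: int
    n_library: int
    base: float = 2.0


@dataclass
class ScanMatrix:
    """Saturation-mutagenesis log2 ratios versus the wild-type peptide.

    Rows are positions relative to the phosphotyrosine, columns amino
    acids; the wild-type residue at every position is exactly 0.
    ``missing`` marks (position, substitution) cells with no usable
    measurement (absent variant or input counts below the floor).
    """

    wt_peptide: str
    values: pd.DataFrame
    missing: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class DomainComparison:
    """Paired per-peptide scores for two domains with ratio flags."""

    table: pd.DataFrame  # columns: score_a, score_b, log2_ratio, flagged
    label_a: str
    label_b: str
    only_a: list[str] = field(default_factory=list)
    only_b: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Cutoff calibration and hit calling
# ---------------------------------------------------------------------------


def _control_scores(et: EnrichmentTable, lib: PeptideLibrary) -> pd.Series:
    ids = [cid for cid in lib.control_ids() if cid in et.ids]
    if not ids:
        raise ValidationError(
            "no tyrosine-free control peptides present in the enrichment "
            "table; cutoff calibration impossible"
        )
    return et.mean.loc[ids]


def calibrate_cutoff(
    et: EnrichmentTable,
    lib: PeptideLibrary,
    max_control_fraction: float = 0.02,
    floor: float = 0.0,
) -> float:
    """Smallest cutoff leaving at most a given fraction of controls above.

    Candidates are the sorted control mean scores plus a configured
    floor; the returned cutoff is the smallest candidate ``c`` such that
    ``fraction{controls with mean score > c} <= max_control_fraction``.
    """
    if not 0.0 < max_control_fraction < 1.0:
        raise ValidationError("max_control_fraction must be in (0, 1)")
    scores = _control_scores(et, lib).to_numpy(dtype=float)
    candidates = np.unique(np.concatenate([[floor], scores[scores > floor]]))
    for c in candidates:
        if np.mean(scores > c) <= max_control_fraction:
            return float(c)
    return float(candidates[-1])  # unreachable: top candidate leaves none above


def control_fraction_above(
    et: EnrichmentTable, lib: PeptideLibrary, cutoff: float
) -> float:
    """Fraction of tyrosine-free controls with mean score above cutoff."""
    scores = _control_scores(et, lib)
    return float((scores > cutoff).mean())


def call_hits(
    et: EnrichmentTable,
    lib: PeptideLibrary,
    cutoff: float,
    mode: str = "mean",
) -> HitSet:
    """Call single-tyrosine, non-control peptides above the cutoff.

    ``mode='mean'`` (default) compares the mean score over replicates;
    ``mode='per_replicate'`` requires every replicate score to exceed
    the cutoff.
    """
    if cutoff < 0:
        raise ValidationError("cutoff must be non-negative")
    if mode not in {"mean", "per_replicate"}:
        raise ValidationError(f"unknown hit-calling mode {mode!r}")
    eligible = [pid for pid in lib.single_tyrosine_ids() if pid in et.ids]
    if mode == "mean":
        above = et.mean.loc[eligible] > cutoff
    else:
        sub = et.scores.loc[eligible]
        above = sub.gt(cutoff) | sub.isna()
        above = above.all(axis=1) & sub.notna().any(axis=1)
    hits = frozenset(pd.Index(eligible)[above.to_numpy()])
    try:
        fpr = control_fraction_above(et, lib, cutoff)
    except ValidationError:
        fpr = 0.0
    return HitSet(
        domain_label=et.domain_label,
        cutoff=float(cutoff),
        hit_ids=hits,
        control_fpr_at_cutoff=fpr,
    )


def hit_overlap(sets: list[HitSet]) -> OverlapReport:
    """Exact region counts of the Venn decomposition of ≥2 hit sets."""
    if len(sets) < 2:
        raise ValidationError("hit_overlap requires at least two sets")
    labels = tuple(s.domain_label for s in sets)
    if len(set(labels)) != len(labels):
        raise ValidationError("hit sets must carry distinct domain labels")
    membership: dict[str, set[str]] = {}
    for s in sets:
        for pid in s.hit_ids:
            membership.setdefault(pid, set()).add(s.domain_label)
    region_counts: dict[tuple[str, ...], int] = {}
    for owners in membership.values():
        key = tuple(sorted(owners))
        region_counts[key] = region_counts.get(key, 0) + 1
    return OverlapReport(
        labels=labels,
        region_counts=region_counts,
        union_size=len(membership),
    )


# ---------------------------------------------------------------------------
# Logo matrix
# ---------------------------------------------------------------------------


def _position_counts(
    entries, positions: list[int]
) -> tuple[pd.DataFrame, pd.Series]:
    """Count residues at each position relative to the phosphotyrosine."""
    counts = pd.DataFrame(
        0, index=pd.Index(positions, name="position"),
        columns=list(AMINO_ACIDS), dtype=float,
    )
    for e in entries:
        if e.phospho_index is None:
            continue
        for p in positions:
            i = e.phospho_index + p
            if 0 <= i < len(e.peptide):
                counts.at[p, e.peptide[i]] += 1
    return counts, counts.sum(axis=1)


def logo_matrix(
    hits: HitSet,
    lib: PeptideLibrary,
    pseudocount: float = 1.0,
    window: tuple[int, int] = (-5, 5),
    base: float = 2.0,
) -> LogoMatrix:
    """Log-odds of hit-set versus library amino-acid composition.

    For position p and amino acid a,
    ``value = log_b((n_hit + pc) / (N_hit + 20 pc))
            - log_b((n_lib + pc) / (N_lib + 20 pc))``
    where counts are taken over peptides aligned on their
    phosphotyrosine, N is the per-position total, and the background is
    the full single-tyrosine library. Position 0 (the pTyr itself) is
    excluded; the window is clipped to the library's peptide length.
    """
    if len(hits) == 0:
        raise ValidationError("logo_matrix requires a non-empty hit set")
    background_ids = set(lib.single_tyrosine_ids())
    if not background_ids:
        raise ValidationError("library has no single-tyrosine peptides")
    # clip the window to offsets the aligned library actually covers
    spans = [
        (-e.phospho_index, len(e.peptide) - 1 - e.phospho_index)
        for e in lib.entries
        if e.id in background_ids and e.phospho_index is not None
    ]
    span_lo = min(s[0] for s in spans)
    span_hi = max(s[1] for s in spans)
    lo, hi = window
    positions = [p for p in range(max(lo, span_lo), min(hi, span_hi) + 1)
                 if p != 0]
    hit_entries = [lib[pid] for pid in hits.hit_ids if pid in background_ids]
    lib_entries = [lib[pid] for pid in background_ids]
    if not hit_entries:
        raise ValidationError("no hit peptides found in the library")

    n_hit, tot_hit = _position_counts(hit_entries, positions)
    n_lib, tot_lib = _position_counts(lib_entries, positions)
    k = len(AMINO_ACIDS)
    f_hit = (n_hit + pseudocount).div(tot_hit + k * pseudocount, axis=0)
    f_lib = (n_lib + pseudocount).div(tot_lib + k * pseudocount, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (np.log(f_hit / f_lib) / np.log(base)).astype(float)
    # at pseudocount 0, residues absent from both sets give 0/0; they
    # carry no evidence either way — define them as no enrichment
    values[values.isna() & (n_hit == 0) & (n_lib == 0)] = 0.0
    return LogoMatrix(
        values=values,
        pseudocount=pseudocount,
        n_enriched=len(hit_entries),
        n_library=len(lib_entries),
        base=base,
    )


# ---------------------------------------------------------------------------
# Scanning-mutagenesis matrix
# ---------------------------------------------------------------------------


def scan_matrix(
    et: EnrichmentTable,
    lib: PeptideLibrary,
    wt_id: str,
    min_input_count: int | None = None,
    input_counts: pd.Series | None = None,
) -> ScanMatrix:
    """Log2 enrichment ratio of every single substitution versus wild type.

    Variants are identified by their single mismatch against the
    wild-type peptide; positions are indexed relative to the
    phosphotyrosine. Variants absent from the table, or whose input
    counts fall below ``min_input_count``, are flagged missing (NaN)
    rather than scored. The cell for the wild-type residue at each
    position is exactly 0 by construction.
    """
    if wt_id not in lib or wt_id not in et.ids:
        raise ValidationError(f"wild-type peptide {wt_id!r} not found")
    wt = lib[wt_id]
    wt_score = float(et.mean.loc[wt_id])
    if not wt_score > 0:
        raise ValidationError("wild-type enrichment score must be positive")
    if wt.phospho_index is None:
        raise ValidationError("wild-type peptide must have a phospho_index")

    positions = [i - wt.phospho_index for i in range(len(wt.peptide))]
    values = pd.DataFrame(
        np.nan, index=pd.Index(positions, name="position"),
        columns=list(AMINO_ACIDS), dtype=float,
    )
    missing = pd.DataFrame(True, index=values.index, columns=values.columns)
    for i, aa in enumerate(wt.peptide):
        p = i - wt.phospho_index
        values.at[p, aa] = 0.0
        missing.at[p, aa] = False

    for e in lib.entries:
        if e.category != "scan_variant" or e.id == wt_id:
            continue
        diffs = [i for i, (a, b) in enumerate(zip(e.peptide, wt.peptide))
                 if a != b]
        if len(diffs) != 1:
            raise ValidationError(
                f"scan variant {e.id!r} is not a single substitution of "
                f"the wild-type peptide"
            )
        i = diffs[0]
        p = i - wt.phospho_index
        sub = e.peptide[i]
        if e.id not in et.ids or pd.isna(et.mean.loc[e.id]):
            continue
        if (
            min_input_count is not None
            and input_counts is not None
            and input_counts.get(e.id, 0) < min_input_count
        ):
            continue
        score = float(et.mean.loc[e.id])
        values.at[p, sub] = float(np.log2(score / wt_score))
        missing.at[p, sub] = False

    return ScanMatrix(wt_peptide=wt.peptide, values=values, missing=missing)


def render_logo(logo: LogoMatrix, path, title: str = "") -> None:
    """Render a LogoMatrix as a letter-height chart (convenience only).

    Letters above the axis are enriched in the hit set relative to the
    library, letters below are depleted; heights are the log2 ratios.
    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(logo.values), 3.0))
    for xi, pos in enumerate(logo.values.index):
        row = logo.values.loc[pos].dropna().sort_values()
        y_pos = y_neg = 0.0
        for aa, value in row.items():
            if value == 0.0:
                continue
            y0 = y_pos if value > 0 else y_neg - abs(value)
            ax.text(xi, y0 + abs(value) / 2, aa, ha="center", va="center",
                    fontsize=7 + 2 * min(abs(value), 2.0))
            if value > 0:
                y_pos += value
            else:
                y_neg -= abs(value)
    ax.set_xticks(range(len(logo.values)))
    ax.set_xticklabels([f"{p:+d}" for p in logo.values.index])
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xlabel("position relative to pTyr")
    ax.set_ylabel(f"log{logo.base:g}(hit / library)")
    if title:
        ax.set_title(title)
    lim = float(np.nanmax(np.abs(logo.values.to_numpy()))) * 20 or 1.0
    ax.set_ylim(-lim, lim)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Cross-domain comparison
# ---------------------------------------------------------------------------


def compare_domains(
    et_a: EnrichmentTable,
    et_b: EnrichmentTable,
    log2_ratio_threshold: float = 1.0,
) -> DomainComparison:
    """Pair per-peptide scores of two domains and flag disproportionate ones.

    Peptides present in only one table are excluded from the pairing and
    reported. A peptide is flagged when ``|log2(score_b / score_a)|``
    exceeds the threshold.
    """
    shared = et_a.ids.intersection(et_b.ids)
    if len(shared) == 0:
        raise ValidationError("no shared peptides between the two tables")
    a = et_a.mean.loc[shared]
    b = et_b.mean.loc[shared]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(b.to_numpy() / a.to_numpy())
    table = pd.DataFrame(
        {"score_a": a, "score_b": b, "log2_ratio": ratio}, index=shared
    )
    table["flagged"] = np.abs(table["log2_ratio"]) > log2_ratio_threshold
    return DomainComparison(
        table=table,
        label_a=et_a.domain_label,
        label_b=et_b.domain_label,
        only_a=sorted(et_a.ids.difference(et_b.ids)),
        only_b=sorted(et_b.ids.difference(et_a.ids)),
    )
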