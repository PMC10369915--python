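"""Frequencies and per-peptide enrichment scores.

The screen statistic is a plain frequency ratio: the frequency of a
peptide in the SH2-selected sequencing sample divided by its frequency in
the unselected input sample. A pseudocount (default 1 read per peptide in
both samples) keeps dropout peptides finite while leaving well-sampled
peptides essentially unchanged. Replicates are averaged on the score
scale; peptides from distinct libraries screened under the same
conditions are concatenated, each keeping its own replicate count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library_io import CountTable, PeptideLibrary, ValidationError, _read_meta

__all__ = [
    "FrequencyTable",
    "EnrichmentTable",
    "frequencies",
    "enrichment_scores",
    "combine",
    "read_enrichment_table",
]


@dataclass
class FrequencyTable:
    """Pseudocount-smoothed peptide frequencies for one sample."""

    library_name: str
    sample_label: str
    freqs: pd.Series
    pseudocount: float

    def __post_init__(self) -> None:
        total = float(self.freqs.sum())
        if len(self.freqs) and abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"frequencies must sum to 1 (got {total:.12f})"
            )


@dataclass
class EnrichmentTable:
    """Per-peptide enrichment scores with replicate structure.

    ``scores`` is a DataFrame indexed by peptide id with one column per
    replicate; NaN marks a peptide absent from that replicate (e.g. a
    peptide screened in only one library). The mean is the arithmetic
    mean over the replicates the peptide actually has.
    """

    domain_label: str
    scores: pd.DataFrame
    source_libraries: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        if vals.size and not np.all(np.isnan(vals)) and np.nanmin(vals) < 0:
            raise ValidationError("enrichment scores must be non-negative")

    @property
    def mean(self) -> pd.Series:
        return self.scores.mean(axis=1, skipna=True)

    @property
    def n_replicates(self) -> pd.Series:
        return self.scores.notna().sum(axis=1)

    @property
    def ids(self) -> pd.Index:
        return self.scores.index


def frequencies(ct: CountTable, pseudocount: float = 1.0) -> FrequencyTable:
    """Convert counts to frequencies: ``(count + pc) / Σ (count + pc)``."""
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    counts = ct.as_series().astype(float)
    if ct.total_matched == 0 and pseudocount == 0:
        raise ValidationError(
            "all counts are zero and pseudocount is zero: frequencies "
            "are undefined"
        )
    smoothed = counts + pseudocount
    return FrequencyTable(
        library_name=ct.library_name,
        sample_label=ct.sample_label,
        freqs=smoothed / smoothed.sum(),
        pseudocount=pseudocount,
    )


def enrichment_scores(
    input_ft: FrequencyTable,
    selected_ft: FrequencyTable,
    domain_label: str = "",
    replicate: str = "rep1",
) -> EnrichmentTable:
    """Single-replicate enrichment: selected frequency / input frequency."""
    if input_ft.library_name != selected_ft.library_name:
        raise ValidationError(
            f"library mismatch: input is {input_ft.library_name!r}, "
            f"selected is {selected_ft.library_name!r}"
        )
    if not input_ft.freqs.index.equals(selected_ft.freqs.index):
        selected = selected_ft.freqs.reindex(input_ft.freqs.index)
        if selected.isna().any():
            raise ValidationError("selected sample is missing peptides")
    else:
        selected = selected_ft.freqs
    if (input_ft.freqs <= 0).any():
        raise ValidationError(
            "input frequencies must be positive for every scored peptide; "
            "use a positive pseudocount"
        )
    scores = selected / input_ft.freqs
    return EnrichmentTable(
        domain_label=domain_label,
        scores=scores.to_frame(replicate),
        source_libraries=[input_ft.library_name],
    )


def combine(
    tables: list[EnrichmentTable],
    lib: PeptideLibrary | None = None,
    multi_tyr_filter: bool = False,
) -> EnrichmentTable:
    """Pool replicates within a library and concatenate across libraries.

    Tables sharing a source library are pooled as replicates (columns);
    tables from distinct libraries are concatenated by peptide id, which
    must not collide. With ``multi_tyr_filter`` peptides whose sequence
    contains more than one tyrosine are dropped (tyrosine-free controls
    are retained for cutoff calibration); this requires ``lib``.
    """
    if not tables:
        raise ValidationError("no enrichment tables to combine")
    labels = {t.domain_label for t in tables}
    if len(labels) > 1:
        raise ValidationError(f"conflicting domain labels: {sorted(labels)}")

    by_library: dict[str, list[pd.DataFrame]] = {}
    for t in tables:
        key = "+".join(t.source_libraries)
        by_library.setdefault(key, []).append(t.scores)

    blocks = []
    for key, frames in by_library.items():
        reps = []
        for i, frame in enumerate(frames, start=1):
            reps.append(frame.set_axis(
                [f"{key}:rep{i}:{c}" for c in frame.columns], axis=1))
        blocks.append(pd.concat(reps, axis=1))

    seen: set[str] = set()
    for block in blocks:
        clash = seen & set(block.index)
        if clash:
            raise ValidationError(
                f"peptide id collisions across libraries: {sorted(clash)[:5]}"
            )
        seen |= set(block.index)
    # column union across libraries; NaN where a peptide lacks a replicate
    merged = pd.concat(blocks, axis=0, join="outer")

    if multi_tyr_filter:
        if lib is None:
            raise ValidationError("multi_tyr_filter requires the library")
        keep = [
            pid for pid in merged.index
            if pid in lib and lib[pid].n_tyrosines <= 1
        ]
        merged = merged.loc[keep]

    return EnrichmentTable(
        domain_label=tables[0].domain_label,
        scores=merged,
        source_libraries=sorted(
            {name for t in tables for name in t.source_libraries}
        ),
    )


def read_enrichment_table(path) -> EnrichmentTable:
    """Read back a TSV written by :func:`sh2screen.library_io.write_table`."""
    import json

    meta = _read_meta(path)
    if meta.get("type") != "EnrichmentTable":
        raise ValidationError(f"{path} is not an EnrichmentTable file")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    df = df.set_index("id") if "id" in df.columns else df
    replicates = json.loads(meta["replicates"])
    scores = df[replicates] if len(df) else pd.DataFrame(
        columns=replicates, index=pd.Index([], name="id"), dtype=float
    )
    return EnrichmentTable(
        domain_label=meta["domain_label"],
        scores=scores,
        source_libraries=json.loads(meta["source_libraries"]),
    )
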