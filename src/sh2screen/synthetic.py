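"""Synthetic screens and titrations with known ground truth.

The selection experiment is modeled as a single multiplicative
reweighting: input counts are drawn multinomially from the input
frequencies, and selected counts multinomially with probabilities
proportional to input frequency × selection weight. A weight of 1.0 is
neutral; tyrosine-free controls default to weight 1.0 so they pass
through at background. One round of reweighting reproduces the
statistical structure the enrichment-score pipeline assumes.

Titrations are generated by the same forward models the fitting code
uses (exact ligand-depletion quadratic, exact competitive cubic,
hyperbolic activation) plus additive zero-mean Gaussian noise —
plate-reader-like signal noise, not counting noise. All randomness flows
from one explicit seed per call; there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activation import ActivationDataset, _hill_rate
from .binding import TitrationDataset, _competition_signal, _direct_signal
from .library_io import (
    AMINO_ACIDS,
    CountTable,
    PeptideEntry,
    PeptideLibrary,
    ValidationError,
)

__all__ = [
    "ScreenTruth",
    "TitrationTruth",
    "simulate_screen",
    "simulate_titration",
    "make_fixture_library",
    "weights_from_position_preferences",
]

_NON_TYR = AMINO_ACIDS.replace("Y", "")


@dataclass
class ScreenTruth:
    """Ground-truth selection weights and sequencing depths for a screen."""

    weights: dict[str, float]
    depth_input: int = 1_000_000
    depth_selected: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise ValidationError("selection weights must be positive")
        if self.depth_input <= 0 or self.depth_selected <= 0:
            raise ValidationError("sequencing depths must be positive")


@dataclass
class TitrationTruth:
    """Ground-truth parameters for a simulated titration.

    ``model`` is one of ``direct`` (params: kd, probe_total,
    signal_free, signal_bound), ``competition`` (params: ki, probe_kd,
    receptor_total, probe_total, signal_free, signal_bound) or
    ``activation`` (params: ec50, rate_basal, rate_max, optional hill).
    Concentrations and constants in µM, noise_sd in signal units.
    """

    model: str
    parameters: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in {"direct", "competition", "activation"}:
            raise ValidationError(f"unknown titration model {self.model!r}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        for key in ("kd", "ki", "ec50", "probe_kd"):
            if key in self.parameters and not self.parameters[key] > 0:
                raise ValidationError(f"parameter {key} must be positive")


def neutral_truth(lib: PeptideLibrary, seed: int = 0,
                  depth_input: int = 1_000_000,
                  depth_selected: int = 1_000_000) -> ScreenTruth:
    """All-neutral weights (1.0 everywhere), for null screens."""
    return ScreenTruth(
        weights={pid: 1.0 for pid in lib.ids},
        depth_input=depth_input, depth_selected=depth_selected, seed=seed,
    )


def simulate_screen(
    lib: PeptideLibrary,
    truth: ScreenTruth,
    input_freqs: dict[str, float] | None = None,
) -> tuple[CountTable, CountTable]:
    """Draw (input, selected) count tables for one selection round.

    Input counts ~ Multinomial(depth_input, input_freqs); selected
    counts ~ Multinomial(depth_selected, p ∝ input_freq × weight).
    Deterministic given ``truth.seed``.
    """
    ids = lib.ids
    missing = [pid for pid in ids if pid not in truth.weights]
    if missing:
        raise ValidationError(
            f"truth weights missing for peptides: {missing[:5]}"
        )
    if input_freqs is None:
        p_in = np.full(len(ids), 1.0 / len(ids))
    else:
        p_in = np.array([input_freqs[pid] for pid in ids], dtype=float)
        if np.any(p_in < 0) or p_in.sum() <= 0:
            raise ValidationError("input frequencies must be non-negative "
                                  "and sum to a positive value")
        p_in = p_in / p_in.sum()
    w = np.array([truth.weights[pid] for pid in ids], dtype=float)
    p_sel = p_in * w
    p_sel = p_sel / p_sel.sum()

    rng = np.random.default_rng(truth.seed)
    counts_in = rng.multinomial(truth.depth_input, p_in)
    counts_sel = rng.multinomial(truth.depth_selected, p_sel)

    def _table(counts: np.ndarray, label: str, depth: int) -> CountTable:
        return CountTable(
            library_name=lib.name,
            sample_label=label,
            counts=dict(zip(ids, (int(c) for c in counts))),
            total_matched=int(depth),
            total_reads=int(depth),
            discarded={},
        )

    return (
        _table(counts_in, "input", truth.depth_input),
        _table(counts_sel, "selected", truth.depth_selected),
    )


def simulate_titration(
    truth: TitrationTruth, concentrations
) -> TitrationDataset | ActivationDataset:
    """Noiseless forward-model signal plus Gaussian noise of sd noise_sd.

    The noiseless curve is computed by the same forward model the
    fitting code uses, so zero-noise datasets are recovered exactly.
    Deterministic given ``truth.seed``.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValidationError("concentrations must be non-negative")
    p = truth.parameters
    try:
        if truth.model == "direct":
            clean = _direct_signal(
                conc, p["probe_total"], p["kd"],
                p["signal_free"], p["signal_bound"],
            )
        elif truth.model == "competition":
            clean = _competition_signal(
                conc, p["receptor_total"], p["probe_total"], p["probe_kd"],
                p["ki"], p["signal_free"], p["signal_bound"],
            )
        else:
            clean = _hill_rate(
                conc, p["ec50"], p["rate_basal"], p["rate_max"],
                p.get("hill", 1.0),
            )
    except KeyError as exc:
        raise ValidationError(
            f"model {truth.model!r} is missing parameter {exc}"
        ) from None

    rng = np.random.default_rng(truth.seed)
    signal = np.asarray(clean, dtype=float)
    if truth.noise_sd > 0:
        signal = signal + rng.normal(0.0, truth.noise_sd, size=conc.shape)

    if truth.model == "activation":
        return ActivationDataset(
            peptide_label="synthetic", concentrations=conc, rates=signal,
        )
    return TitrationDataset(
        mode=truth.model,
        concentrations=conc,
        signal=signal,
        probe_total=p["probe_total"],
        receptor_total=p.get("receptor_total"),
        probe_kd=p.get("probe_kd"),
    )


def make_fixture_library(
    n_sites: int,
    n_controls: int,
    peptide_length: int,
    seed: int = 0,
    name: str = "fixture",
) -> PeptideLibrary:
    """Random single-tyrosine peptides (central Y) plus Tyr-free controls.

    Deterministic given ``seed``. ``n_controls`` must be ≥ 1 because
    cutoff calibration needs at least one tyrosine-free control.
    """
    if peptide_length < 1:
        raise ValidationError("peptide_length must be at least 1")
    if n_controls < 1:
        raise ValidationError(
            "need at least one tyrosine-free control for cutoff calibration"
        )
    rng = np.random.default_rng(seed)
    center = peptide_length // 2
    entries = []
    for i in range(n_sites):
        residues = rng.choice(list(_NON_TYR), size=peptide_length)
        residues[center] = "Y"
        entries.append(
            PeptideEntry(
                id=f"site_{i + 1:04d}",
                peptide="".join(residues),
                category="wildtype_site",
                phospho_index=center,
            )
        )
    for i in range(n_controls):
        residues = rng.choice(list(_NON_TYR), size=peptide_length)
        entries.append(
            PeptideEntry(
                id=f"ctrl_{i + 1:04d}",
                peptide="".join(residues),
                category="tyr_free_control",
            )
        )
    return PeptideLibrary(
        name=name, entries=tuple(entries), peptide_length=peptide_length
    )


def weights_from_position_preferences(
    lib: PeptideLibrary,
    preferences: dict[tuple[int, str], float],
    base_weight: float = 1.0,
) -> dict[str, float]:
    """Multiplicative position-weight truth for a library.

    ``preferences`` maps (position relative to pTyr, amino acid) to a
    multiplicative factor (> 1 favored, < 1 disfavored). A peptide's
    weight is ``base_weight × Π factors`` over its residues;
    tyrosine-free controls get weight 1.0 (background).
    """
    weights: dict[str, float] = {}
    for e in lib.entries:
        if e.phospho_index is None:
            weights[e.id] = 1.0
            continue
        w = base_weight
        for (pos, aa), factor in preferences.items():
            i = e.phospho_index + pos
            if 0 <= i < len(e.peptide) and e.peptide[i] == aa:
                w *= factor
        weights[e.id] = w
    return weights
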