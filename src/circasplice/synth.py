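"""Synthetic probe-level exon-array data with known planted structure.

Generates probe x sample intensity matrices with additive chip + probe
structure on the log2 scale, 24-h sinusoidal transcript rhythms, probeset-
restricted circadian (24-h) or ultradian (12-h) splice departures, matched
pseudo-Ct QPCR tables, and promoter sequence sets with planted motifs.
Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SyntheticDataset",
    "generate_dataset",
    "generate_qpcr",
    "generate_promoters",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the probe-level simulation.

    All amplitudes and standard deviations are on the log2 scale. Phases of
    planted rhythms are drawn from ``ct_grid`` by default so that planted
    acrophases are exactly recoverable from the 4-point sampling design;
    set ``on_grid_phases=False`` for continuous phases.
    """

    n_clusters: int = 100
    probesets_per_cluster: int = 10
    probes_per_probeset: int = 4
    ct_grid: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0)
    n_reps: int = 3
    baseline_log2: float = 7.0
    transcript_amp_log2: float = 0.5
    frac_rhythmic_transcripts: float = 0.5
    frac_circadian_splice: float = 0.05
    splice_amp_log2: float = 0.5
    frac_ultradian_splice: float = 0.0
    probe_affinity_sd: float = 0.5
    noise_sd: float = 0.2
    on_grid_phases: bool = True
    background_offset: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_clusters", "probesets_per_cluster", "probes_per_probeset"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2 (the screen needs within-group variance)")
        if len(self.ct_grid) == 0:
            raise ValueError("ct_grid must not be empty")
        grid = list(self.ct_grid)
        if grid != sorted(grid) or len(set(grid)) != len(grid):
            raise ValueError("ct_grid must be strictly increasing")
        if not all(0.0 <= t < 24.0 for t in grid):
            raise ValueError("ct_grid values must lie in [0, 24)")
        for name in (
            "frac_rhythmic_transcripts",
            "frac_circadian_splice",
            "frac_ultradian_splice",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_circadian_splice + self.frac_ultradian_splice > 1.0:
            raise ValueError("circadian and ultradian splice fractions must sum to <= 1")
        for name in ("probe_affinity_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.background_offset < 0:
            raise ValueError("background_offset must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth for one probeset."""

    probeset_id: str
    is_circadian_splice: bool
    splice_phase: float
    splice_amp_log2: float
    is_ultradian: bool
    cluster_is_rhythmic: bool
    transcript_phase: float

    def __post_init__(self) -> None:
        if self.is_circadian_splice and self.is_ultradian:
            raise ValueError("circadian and ultradian splice flags are mutually exclusive")


@dataclass
class SyntheticDataset:
    """A generated dataset bundle: layout, intensities, design, and truth."""

    layout: pd.DataFrame
    intensities: pd.DataFrame
    design: pd.DataFrame
    truth: list[TruthRecord]
    config: SimulationConfig

    @property
    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(t) for t in self.truth])


def _planted_count(frac: float, total: int, rng: np.random.Generator) -> int:
    """floor(frac*total), with the fractional remainder resolved by seeded draw."""
    base = int(np.floor(frac * total))
    rem = frac * total - base
    if rem > 0 and rng.random() < rem:
        base += 1
    return min(base, total)


def _draw_phase(rng: np.random.Generator, config: SimulationConfig) -> float:
    if config.on_grid_phases:
        return float(rng.choice(config.ct_grid))
    return float(rng.uniform(0.0, 24.0))


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Simulate a probe-level dataset under the additive log2 signal model.

    log2 I_k(t) = baseline_g + A_g cos(2pi (t - phi_g)/24) + p_k + delta_j(t) + eps
    where delta_j is a 24-h (circadian splice) or 12-h (ultradian) cosine for
    flagged probesets and zero otherwise. Intensities are returned on the
    linear scale.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_ps_total = config.n_clusters * config.probesets_per_cluster
    n_circ = _planted_count(config.frac_circadian_splice, n_ps_total, rng)
    n_ult = _planted_count(config.frac_ultradian_splice, n_ps_total - n_circ, rng)
    n_rhy = _planted_count(config.frac_rhythmic_transcripts, config.n_clusters, rng)

    flagged = rng.choice(n_ps_total, size=n_circ + n_ult, replace=False)
    circ_set = set(flagged[:n_circ].tolist())
    ult_set = set(flagged[n_circ:].tolist())
    rhythmic_clusters = set(rng.choice(config.n_clusters, size=n_rhy, replace=False).tolist())

    samples = []
    design_rows = []
    for ct in config.ct_grid:
        for rep in range(1, config.n_reps + 1):
            sid = f"CT{int(ct):02d}_R{rep}"
            samples.append(sid)
            design_rows.append(
                {
                    "sample_id": sid,
                    "circadian_time": float(ct),
                    "tissue": "liver",
                    "feeding": "fed",
                    "genotype": "wt",
                    "replicate": rep,
                }
            )
    design = pd.DataFrame(design_rows)
    t = np.repeat(np.asarray(config.ct_grid, dtype=float), config.n_reps)

    layout_rows = []
    truth: list[TruthRecord] = []
    blocks = []
    probe_ids = []
    ps_global = 0
    for g in range(config.n_clusters):
        cluster_id = f"TC{g + 1:04d}"
        is_rhythmic = g in rhythmic_clusters
        phi_g = _draw_phase(rng, config)
        amp_g = config.transcript_amp_log2 if is_rhythmic else 0.0
        transcript = config.baseline_log2 + amp_g * np.cos(2 * np.pi * (t - phi_g) / 24.0)
        for j in range(config.probesets_per_cluster):
            probeset_id = f"{cluster_id}_PS{j + 1:02d}"
            is_circ = ps_global in circ_set
            is_ult = ps_global in ult_set
            if is_circ or is_ult:
                phi_j = _draw_phase(rng, config)
                period = 24.0 if is_circ else 12.0
                amp_j = config.splice_amp_log2
                delta = amp_j * np.cos(2 * np.pi * (t - phi_j) / period)
            else:
                phi_j = 0.0
                amp_j = 0.0
                delta = np.zeros_like(t)
            truth.append(
                TruthRecord(
                    probeset_id=probeset_id,
                    is_circadian_splice=is_circ,
                    splice_phase=phi_j,
                    splice_amp_log2=amp_j,
                    is_ultradian=is_ult,
                    cluster_is_rhythmic=is_rhythmic,
                    transcript_phase=phi_g,
                )
            )
            p_k = rng.normal(0.0, config.probe_affinity_sd, size=config.probes_per_probeset)
            eps = rng.normal(0.0, config.noise_sd, size=(config.probes_per_probeset, len(t)))
            block = transcript[None, :] + delta[None, :] + p_k[:, None] + eps
            blocks.append(block)
            for k in range(config.probes_per_probeset):
                pid = f"{probeset_id}_P{k + 1}"
                probe_ids.append(pid)
                layout_rows.append(
                    {"probe_id": pid, "probeset_id": probeset_id, "cluster_id": cluster_id}
                )
            ps_global += 1

    log2_matrix = np.vstack(blocks)
    linear = np.exp2(log2_matrix) + config.background_offset
    intensities = pd.DataFrame(linear, index=pd.Index(probe_ids, name="probe_id"), columns=samples)
    layout = pd.DataFrame(layout_rows)
    return SyntheticDataset(
        layout=layout, intensities=intensities, design=design, truth=truth, config=config
    )


def _latent_log2(
    dataset: SyntheticDataset, probeset_id: str, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (exon, transcript) log2 signals for one probeset at `times`."""
    config = dataset.config
    rec = next(t for t in dataset.truth if t.probeset_id == probeset_id)
    amp_g = config.transcript_amp_log2 if rec.cluster_is_rhythmic else 0.0
    transcript = config.baseline_log2 + amp_g * np.cos(
        2 * np.pi * (times - rec.transcript_phase) / 24.0
    )
    if rec.is_circadian_splice or rec.is_ultradian:
        period = 24.0 if rec.is_circadian_splice else 12.0
        delta = rec.splice_amp_log2 * np.cos(2 * np.pi * (times - rec.splice_phase) / period)
    else:
        delta = np.zeros_like(times)
    return transcript + delta, transcript


def generate_qpcr(
    dataset: SyntheticDataset,
    targets: Sequence[str],
    efficiency: float = 2.0,
    ct_offset: float = 30.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit pseudo-Ct QPCR rows consistent with the latent log2 signals.

    For each target probeset, an exon-specific assay (transcript rhythm plus
    splice departure), a transcript-level assay, and one shared constant
    normalizer assay are produced: Ct = ct_offset - latent_log2/log2(efficiency).
    """
    if efficiency <= 1.0:
        raise ValueError(f"efficiency must be > 1, got {efficiency}")
    known = set(dataset.layout["probeset_id"])
    missing = [t for t in targets if t not in known]
    if missing:
        raise KeyError(f"targets not in layout: {missing}")
    rng = np.random.default_rng(seed)
    times = dataset.design["circadian_time"].to_numpy(dtype=float)
    sample_ids = dataset.design["sample_id"].to_numpy()
    slope = 1.0 / np.log2(efficiency)

    rows = []

    def _emit(target: str, log2_signal: np.ndarray) -> None:
        ct = ct_offset - log2_signal * slope
        if noise_sd > 0:
            ct = ct + rng.normal(0.0, noise_sd, size=ct.shape)
        for sid, v in zip(sample_ids, ct):
            rows.append(
                {
                    "sample_id": sid,
                    "target": target,
                    "mode": "ct",
                    "value": float(v),
                    "efficiency": efficiency,
                }
            )

    for ps in targets:
        exon, transcript = _latent_log2(dataset, ps, times)
        _emit(f"{ps}_exon", exon)
        _emit(f"{ps}_transcript", transcript)
    _emit("normalizer", np.full_like(times, dataset.config.baseline_log2))
    return pd.DataFrame(rows)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def generate_promoters(
    n_fg: int,
    n_bg: int,
    length: int,
    planted_motif: str,
    frac_fg_with_motif: float,
    frac_bg_with_motif: float,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], pd.DataFrame]:
    """Uniform-random ACGT promoter sets with a consensus motif planted.

    Returns (foreground records, background records, truth table); records
    are (id, sequence) pairs and the truth table lists the planted 1-based
    position and strand (or has_motif=False) for every sequence.
    """
    motif = planted_motif.upper()
    if length < len(motif):
        raise ValueError(f"length {length} < motif width {len(motif)}")
    if not set(motif) <= set("ACGT"):
        raise ValueError("planted motif must be over ACGT")
    for name, frac in (("frac_fg_with_motif", frac_fg_with_motif), ("frac_bg_with_motif", frac_bg_with_motif)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)

    truth_rows = []

    def _make_set(prefix: str, n: int, frac: float) -> list[tuple[str, str]]:
        n_with = _planted_count(frac, n, rng)
        with_motif = set(rng.choice(n, size=n_with, replace=False).tolist()) if n else set()
        records = []
        for i in range(n):
            sid = f"{prefix}{i + 1:03d}"
            seq = _random_seq(rng, length)
            if i in with_motif:
                pos = int(rng.integers(0, length - len(motif) + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                insert = motif if strand == "+" else motif.translate(_COMPLEMENT)[::-1]
                seq = seq[:pos] + insert + seq[pos + len(motif):]
                truth_rows.append(
                    {"seq_id": sid, "set": prefix, "has_motif": True,
                     "position": pos + 1, "strand": strand}
                )
            else:
                truth_rows.append(
                    {"seq_id": sid, "set": prefix, "has_motif": False,
                     "position": 0, "strand": "."}
                )
            records.append((sid, seq))
        return records

    fg = _make_set("fg", n_fg, frac_fg_with_motif)
    bg = _make_set("bg", n_bg, frac_bg_with_motif)
    return fg, bg, pd.DataFrame(truth_rows)
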