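"""Replication geometry and genome-structure statistics.

Replichores are defined from the replication origin (*ori*) and a terminus
(*ter*) placed half the replicon length away.  On replichore 1 (the
ascending-coordinate arc ori -> ter) the top (+) strand is the leading
strand; on replichore 2 it is the lagging strand, and the bottom strand is
the mirror image.  The insertion-bias (IB) score of a set of intron calls is
n_lagging / n_leading (>= 5 strong, 2 to < 5 moderate lagging-strand bias).

GC skew is (G - C)/(G + C) per window (default 10 kb); the GC skew index
(GCSI) summarises how strongly a replicon shows the canonical two-replichore
skew structure, on [0, 1], combining the spectral prominence of the
single-period component of the windowed skew with the amplitude of the
cumulative skew.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import GenomeRecord

log = logging.getLogger("g2i")

SKEW_WINDOW = 10_000
GCSI_WINDOWS = 4096
GCSI_SR_NORM = 6000.0
GCSI_DIST_NORM = 600.0

IB_STRONG = 5.0
IB_MODERATE = 2.0


@dataclass
class ReplicationModel:
    replicon_id: str
    ori: int
    length: int
    ter: int = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.ori < self.length:
            raise ValueError("ori outside replicon")
        self.ter = infer_ter(self.ori, self.length)


@dataclass
class SkewProfile:
    replicon_id: str
    window: int
    skew: np.ndarray
    cumulative: np.ndarray
    flagged_windows: list = field(default_factory=list)  # windows with G+C == 0


@dataclass
class IBResult:
    n_lagging: int
    n_leading: int
    ib_score: float  # math.inf when n_leading == 0 and n_lagging > 0
    category: str  # strong | moderate | weak/none | undefined


def infer_ter(ori: int, length: int) -> int:
    """Terminus = ori + floor(length/2), modulo the replicon length."""
    return (ori + length // 2) % length


def strand_class(position: int, strand: str, model: ReplicationModel) -> str:
    """leading/lagging class of a feature at `position` on `strand`.

    Positions exactly at ori or ter belong to replichore 1.
    """
    arc = (model.ter - model.ori) % model.length
    rel = (position - model.ori) % model.length
    on_rep1 = rel < arc or position == model.ter or position == model.ori
    if strand == "+":
        return "leading" if on_rep1 else "lagging"
    return "lagging" if on_rep1 else "leading"


def ib_score(classes: list[str]) -> IBResult:
    """Insertion-bias score from per-call leading/lagging classes."""
    n_lag = classes.count("lagging")
    n_lead = classes.count("leading")
    if n_lead == 0 and n_lag == 0:
        return IBResult(0, 0, float("nan"), "undefined")
    if n_lead == 0:
        return IBResult(n_lag, 0, math.inf, "strong")
    ib = n_lag / n_lead
    if ib >= IB_STRONG:
        cat = "strong"
    elif ib >= IB_MODERATE:
        cat = "moderate"
    else:
        cat = "weak/none"
    return IBResult(n_lag, n_lead, ib, cat)


def _base_counts(seq: str) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return (arr == ord("G")), (arr == ord("C"))


def _window_skew(seq: str, edges: np.ndarray) -> tuple[np.ndarray, list[int]]:
    is_g, is_c = _base_counts(seq)
    cg = np.concatenate([[0], np.cumsum(is_g)])
    cc = np.concatenate([[0], np.cumsum(is_c)])
    g = cg[edges[1:]] - cg[edges[:-1]]
    c = cc[edges[1:]] - cc[edges[:-1]]
    tot = g + c
    flagged = [int(i) for i in np.nonzero(tot == 0)[0]]
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(tot > 0, (g - c) / np.where(tot > 0, tot, 1), 0.0)
    return skew.astype(float), flagged


def gc_skew_profile(genome: GenomeRecord, window: int = SKEW_WINDOW) -> SkewProfile:
    """(G-C)/(G+C) per window plus the cumulative (prefix-sum) skew.

    N bases are excluded from the counts; a window with no G or C gets skew
    0 and is flagged.  Only full windows are used; a replicon shorter than
    one window falls back to a single window with a warning.
    """
    L = genome.length
    if L < window:
        log.warning("replicon %s shorter than window; single-window fallback", genome.replicon_id)
        edges = np.array([0, L])
        window = L
    else:
        n = L // window
        edges = np.arange(n + 1) * window
    skew, flagged = _window_skew(genome.sequence, edges)
    return SkewProfile(
        replicon_id=genome.replicon_id,
        window=window,
        skew=skew,
        cumulative=np.cumsum(skew),
        flagged_windows=flagged,
    )


def gcsi(
    genome: GenomeRecord,
    n_windows: int = GCSI_WINDOWS,
    sr_norm: float = GCSI_SR_NORM,
    dist_norm: float = GCSI_DIST_NORM,
) -> tuple[float, float, float]:
    """GC skew index on [0, 1]; returns (gcsi, sr, dist).

    The replicon is cut into n_windows equal windows (remainder bases beyond
    the last full window are ignored); sr is the power of the discrete
    Fourier component at frequency 1 relative to the mean power over all
    nonzero frequencies, and dist is the range (max - min) of the cumulative
    windowed skew expressed per window and scaled by 1000.  GCSI =
    sqrt((sr/sr_norm) * (dist/dist_norm)), clipped to [0, 1].
    """
    L = genome.length
    if L < n_windows:
        raise ValueError(f"replicon shorter than {n_windows} windows")
    w = L // n_windows
    edges = np.arange(n_windows + 1) * w
    skew, _ = _window_skew(genome.sequence, edges)
    spectrum = np.fft.rfft(skew)
    power = np.abs(spectrum) ** 2
    mean_power = power[1:].mean()
    sr = float(power[1] / mean_power) if mean_power > 0 else 0.0
    # leading zero makes the walk's range invariant under reverse complement
    cum = np.concatenate([[0.0], np.cumsum(skew)])
    dist = float((cum.max() - cum.min()) / n_windows * 1000.0)
    value = math.sqrt((sr / sr_norm) * (dist / dist_norm))
    return min(1.0, max(0.0, value)), sr, dist


def load_ori_table(path: str) -> dict[str, int]:
    """replicon_id -> ori coordinate (table gives 1-based positions)."""
    out = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out[f[idx["replicon_id"]]] = int(f[idx["ori"]]) - 1
    return out


def plot_skew(profile: SkewProfile, calls=(), path: Optional[str] = None):
    """Windowed and cumulative skew with intron insertion positions marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    x = np.arange(len(profile.skew)) * profile.window
    ax1.plot(x, profile.skew, lw=0.7, color="tab:blue")
    ax1.axhline(0, color="grey", lw=0.5)
    ax1.set_ylabel("GC skew")
    ax2.plot(x, profile.cumulative, lw=1.0, color="tab:orange")
    ax2.set_ylabel("cumulative skew")
    ax2.set_xlabel(f"position (nt), {profile.replicon_id}")
    for c in calls:
        y = 1 if c.strand == "+" else -1
        ax1.plot([c.span[0]], [y * 0.9], marker="v" if y < 0 else "^", color="k", ms=4)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
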