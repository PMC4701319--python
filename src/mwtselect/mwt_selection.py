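"""Mother-wavelet fitness scoring and region-wise selection.

Every candidate wavelet denoises every epoch; the fitness score is the
Pearson cross-correlation XCorr between the band-limited epoch X and its
denoised version Y,

    XCorr(X, Y) = sum((X - mean X)(Y - mean Y))
                  / sqrt(sum((X - mean X)^2) * sum((Y - mean Y)^2)),

a scale-invariant similarity in [-1, 1].  Scores are pooled per scalp
region (all channel x epoch values of the region), compared across the 45
wavelet groups with a one-way ANOVA, and ranked; Duncan's multiple range
test marks which runners-up are statistically indistinguishable from the
winner.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .denoise import denoise_epoch
from .preprocess import EpochSet, RegionMap
from .stats_tests import AnovaResult, DuncanResult, anova_oneway, duncan_mrt
from .wavelet_bank import WaveletSpec, list_candidate_wavelets, DEFAULT_MODE

__all__ = [
    "UndefinedCorrelationError",
    "RegionSelection",
    "SelectionReport",
    "xcorr",
    "score_all",
    "aggregate_by_region",
    "select_best",
    "rank_by_mean",
]

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """Correlation undefined: a constant input gives a zero denominator."""


@dataclass
class RegionSelection:
    region: str
    winner: str
    ranking: list[str]  # wavelet names by descending mean score
    means: dict[str, float]
    sds: dict[str, float]
    anova: AnovaResult
    duncan: DuncanResult
    not_different_from_winner: list[str]


@dataclass
class SelectionReport:
    alpha: float
    regions: dict[str, RegionSelection]

    def to_json(self, **kwargs) -> str:
        payload = {
            "alpha": self.alpha,
            "regions": {
                name: {
                    "winner": sel.winner,
                    "ranking": sel.ranking,
                    "means": sel.means,
                    "sds": sel.sds,
                    "anova": {
                        "F": sel.anova.f_statistic,
                        "df": [sel.anova.df_num, sel.anova.df_den],
                        "p": sel.anova.p_value,
                    },
                    "duncan_letters": sel.duncan.letters,
                    "not_different_from_winner": sel.not_different_from_winner,
                }
                for name, sel in self.regions.items()
            },
        }
        return json.dumps(payload, **kwargs)

    def summary(self) -> str:
        lines = []
        for name, sel in self.regions.items():
            peers = ", ".join(sel.not_different_from_winner) or "none"
            lines.append(
                f"{name}: best wavelet {sel.winner!r} "
                f"(mean XCorr {sel.means[sel.winner]:.4f}); "
                f"not significantly different: {peers}"
            )
        return "\n".join(lines)


def xcorr(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson cross-correlation of two equal-length epochs."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    if den == 0.0:
        raise UndefinedCorrelationError(
            "correlation undefined for constant input"
        )
    return float(np.clip((xc @ yc) / den, -1.0, 1.0))


def score_all(
    epochs: EpochSet,
    bank: Sequence[WaveletSpec] | None = None,
    levels: int = 5,
    mode: str = DEFAULT_MODE,
    rule: str = "sure",
    subject: str = "s01",
) -> pd.DataFrame:
    """Score every (channel, epoch, wavelet) combination.

    Returns a long-format table with columns
    ``subject, channel, epoch, wavelet, xcorr``.  Epochs whose correlation
    is undefined (constant input or constant denoised output) are recorded
    as NaN; the count is logged and downstream pooling drops them.
    """
    if bank is None:
        bank = list_candidate_wavelets()
    records = []
    n_undefined = 0
    # db1 and sym1 are the same (Haar) filter pair: compute once, reuse
    cache_alias = {}
    for w in bank:
        key = tuple(np.round(w.dec_lo, 12))
        for ch in range(epochs.n_channels):
            label = epochs.labels[ch]
            for e in range(epochs.n_epochs):
                x = epochs.epochs[ch, e]
                ck = (key, ch, e, levels, rule)
                if ck in cache_alias:
                    val = cache_alias[ck]
                else:
                    try:
                        y = denoise_epoch(x, w, levels, mode=mode, rule=rule)
                        val = xcorr(x, y)
                    except UndefinedCorrelationError:
                        val = np.nan
                        n_undefined += 1
                    cache_alias[ck] = val
                records.append((subject, label, e, w.name, val))
    if n_undefined:
        logger.warning(
            "%d epoch/wavelet scores undefined (constant input); stored as NaN",
            n_undefined,
        )
    return pd.DataFrame.from_records(
        records, columns=["subject", "channel", "epoch", "wavelet", "xcorr"]
    )


def aggregate_by_region(table: pd.DataFrame, region_map: RegionMap) -> pd.DataFrame:
    """Pool channel x epoch scores into scalp regions.

    Adds a ``region`` column; every channel in the table must be mapped.
    Undefined (NaN) scores are dropped with a logged count.
    """
    mapping = {}
    for ch in table["channel"].unique():
        mapping[ch] = region_map.region_of(ch)  # KeyError for unmapped
    out = table.copy()
    out["region"] = out["channel"].map(mapping)
    n_nan = int(out["xcorr"].isna().sum())
    if n_nan:
        logger.warning("dropping %d undefined scores from the pools", n_nan)
        out = out.dropna(subset=["xcorr"])
    return out


def rank_by_mean(pooled: pd.DataFrame, region: str) -> list[str]:
    """Wavelet names by descending mean score in one region (ties by name)."""
    sub = pooled[pooled["region"] == region]
    means = sub.groupby("wavelet")["xcorr"].mean()
    return sorted(means.index, key=lambda wname: (-means[wname], wname))


def select_best(pooled: pd.DataFrame, alpha: float = 0.05) -> SelectionReport:
    """Per-region winner with ANOVA and Duncan post-hoc annotations."""
    regions = {}
    for region in pooled["region"].unique():
        sub = pooled[pooled["region"] == region]
        groups = {
            wname: grp["xcorr"].to_numpy()
            for wname, grp in sub.groupby("wavelet")
        }
        if len(groups) < 2 or any(g.size < 2 for g in groups.values()):
            raise ValueError(
                f"region {region!r}: need >= 2 wavelet groups with >= 2 scores"
            )
        anova = anova_oneway(groups)
        duncan = duncan_mrt(
            groups, alpha=alpha, mse=anova.mse, df_within=anova.df_den
        )
        ranking = sorted(groups, key=lambda wname: (-groups[wname].mean(), wname))
        winner = ranking[0]
        regions[region] = RegionSelection(
            region=region,
            winner=winner,
            ranking=ranking,
            means={g: float(v.mean()) for g, v in groups.items()},
            sds={g: float(v.std(ddof=1)) for g, v in groups.items()},
            anova=anova,
            duncan=duncan,
            not_different_from_winner=sorted(duncan.not_different_from(winner)),
        )
    return SelectionReport(alpha=alpha, regions=regions)
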