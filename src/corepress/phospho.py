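"""TMT reporter-ion phospho time-course processing.

The fixed-order pipeline is: spectrum retention filtering (a spectrum is
dropped when 5 or more of its 10 reporter channels are missing, or when
every present reporter is below an absolute intensity of 2000), grouping of
spectra into peptides keyed by sequence plus the set of confidently
localised phospho-sites (site localisation probability strictly above
0.95), conversion to per-timepoint fold changes against the untreated
channel, a two-fold regulation screen (any timepoint >= 2-fold up or down,
boundary inclusive) and k-means clustering of the log2 dynamics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

N_CHANNELS = 10
MIN_INTENSITY = 2000.0
MAX_MISSING = 4  # >= 5 missing -> removed
LOCALISATION_CUT = 0.95  # strict: > 0.95 is confident
REGULATION_FOLD = 2.0

#: Default TMT10 channel -> timepoint layout: two reporter channels per
#: timepoint, in acquisition order, for the 0/1.5/5/15/30 min course.
DEFAULT_TIMEPOINTS = (0.0, 1.5, 5.0, 15.0, 30.0)
DEFAULT_CHANNEL_MAP = {i: DEFAULT_TIMEPOINTS[i // 2] for i in range(N_CHANNELS)}

REPORTER_COLS = [f"reporter_{i + 1}" for i in range(N_CHANNELS)]


def filter_spectra(spectra: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the spectrum retention rules; return (retained, rejection log).

    A spectrum is removed iff it has >= 5 missing reporter intensities or
    every present reporter is strictly below 2000.  The rejection log has
    one row per removed spectrum with the triggering reason(s).
    """
    inten = spectra[REPORTER_COLS].to_numpy(dtype=float)
    missing = np.isnan(inten).sum(axis=1)
    too_missing = missing > MAX_MISSING
    with np.errstate(invalid="ignore"):
        present_max = np.nanmax(np.where(np.isnan(inten), -np.inf, inten), axis=1)
    all_low = present_max < MIN_INTENSITY
    removed = too_missing | all_low
    reasons = []
    for tm, al in zip(too_missing, all_low):
        r = []
        if tm:
            r.append("missing_channels")
        if al:
            r.append("all_below_intensity_floor")
        reasons.append(";".join(r))
    log = spectra.loc[removed, ["spectrum_id"]].copy()
    log["reason"] = [r for r, flag in zip(reasons, removed) if flag]
    return spectra.loc[~removed].reset_index(drop=True), log.reset_index(drop=True)


def _confident_sites(site_string: str, probs_string: str) -> tuple[str, ...]:
    """Sites whose localisation probability is strictly above the cutoff."""
    if not site_string or site_string in ("", "-"):
        return ()
    sites = str(site_string).split(";")
    probs = [float(p) for p in str(probs_string).split(";")]
    return tuple(sorted(s for s, p in zip(sites, probs) if p > LOCALISATION_CUT))


def group_peptides(spectra: pd.DataFrame) -> pd.DataFrame:
    """Group filtered spectra into peptides.

    Key = (sequence, set of confidently localised sites); sites at or below
    95% localisation probability are dropped from the key.  Reporter
    channels of spectra sharing a key are aggregated by the median,
    ignoring missing values.
    """
    keys = [
        (row["peptide"], _confident_sites(row["site"], row["localisation_prob"]))
        for _, row in spectra.iterrows()
    ]
    df = spectra.copy()
    df["peptide_key"] = [f"{seq}|{','.join(sites)}" for seq, sites in keys]
    agg = df.groupby("peptide_key")[REPORTER_COLS].median()
    agg["n_spectra"] = df.groupby("peptide_key").size()
    return agg.reset_index()


def profiles_from_peptides(
    peptides: pd.DataFrame,
    channel_map: dict[int, float] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Collapse channels to per-timepoint fold changes relative to t = 0.

    Per timepoint the median over its reporter channels is taken; fold
    change is that median divided by the t = 0 median.  Peptides with no
    data at any timepoint (or zero at t = 0) are excluded and their keys
    returned separately.
    """
    if channel_map is None:
        channel_map = DEFAULT_CHANNEL_MAP
    tps = sorted(set(channel_map.values()))
    t0 = tps[0]
    rows = []
    dropped = []
    for _, row in peptides.iterrows():
        med = {}
        ok = True
        for t in tps:
            chans = [REPORTER_COLS[i] for i, tt in channel_map.items() if tt == t]
            vals = row[chans].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                ok = False
                break
            med[t] = float(np.median(vals))
        if not ok or med[t0] <= 0:
            dropped.append(row["peptide_key"])
            continue
        rows.append(
            {"peptide_key": row["peptide_key"], **{f"fc_{t}": med[t] / med[t0] for t in tps}}
        )
    prof = pd.DataFrame(rows).set_index("peptide_key") if rows else pd.DataFrame(
        columns=[f"fc_{t}" for t in tps]
    )
    return prof, dropped


def regulation_filter(profiles: pd.DataFrame, fold: float = REGULATION_FOLD) -> pd.DataFrame:
    """Retain peptides with at least ``fold``-fold regulation at any timepoint.

    Boundary inclusive: a fold change of exactly 2 (or 0.5) is regulated.
    """
    fc = profiles.to_numpy(dtype=float)
    reg = (fc >= fold).any(axis=1) | (fc <= 1.0 / fold).any(axis=1)
    return profiles.loc[reg]


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int,
    n_restarts: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, float]:
    """K-means clustering of log2 fold-change dynamics.

    Uses k-means++ initialization with the best of ``n_restarts`` runs by
    within-cluster sum of squares.  Returns (assignments, centroids in log2
    space, WSS).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds number of profiles ({len(profiles)})")
    x = np.log2(profiles.to_numpy(dtype=float))
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(x)
    out = pd.DataFrame({"cluster_id": labels + 1}, index=profiles.index)
    return out, km.cluster_centers_, float(km.inertia_)
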