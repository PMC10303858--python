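"""Median-of-ratios normalization and the expression / full-length / subfamily
filters, MilliDiv summaries, and the per-sample retained-intron filter.

Size factors follow the classic median-of-ratios recipe: the reference for a
feature is its geometric mean across samples (features with any zero count
are excluded from the reference), and a sample's factor is the median of its
count/reference ratios.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ExpressedSet:
    """Feature ids passing the expression filters, plus the thresholds used."""

    feature_ids: tuple[str, ...]
    min_mean_reads: float
    min_length: int | None = None
    subfamilies: tuple[str, ...] | None = None

    def __contains__(self, fid: str) -> bool:
        return fid in set(self.feature_ids)

    def __len__(self) -> int:
        return len(self.feature_ids)


def estimate_size_factors(raw: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample column.

    Raises if no feature has all-positive counts (nothing to build the
    reference from — pre-filter the matrix first).
    """
    if raw.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    values = raw.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature with all-positive counts; pre-filter the matrix before "
            "estimating size factors"
        )
    logs = np.log(values[positive])
    log_ref = logs.mean(axis=1, keepdims=True)  # geometric mean in log space
    sf = np.exp(np.median(logs - log_ref, axis=0))
    return pd.Series(sf, index=raw.columns, name="size_factor")


def normalize(raw: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    missing = [s for s in raw.columns if s not in size_factors.index]
    if missing:
        raise ValueError(f"size factors missing for samples: {missing}")
    if (size_factors.loc[list(raw.columns)] <= 0).any():
        raise ValueError("size factors must be positive")
    return raw / size_factors.loc[list(raw.columns)]


def _match_subfamily(subfamily: str, whitelist) -> bool:
    for pat in whitelist:
        if "*" in pat:
            if re.fullmatch(pat.replace("*", ".*"), subfamily):
                return True
        elif subfamily == pat:
            return True
    return False


def select_expressed(
    raw: pd.DataFrame,
    min_mean: float = 200.0,
    min_length: int | None = None,
    subfamilies=None,
    lengths: pd.Series | None = None,
    feature_subfamilies: pd.Series | None = None,
) -> ExpressedSet:
    """Keep features with mean raw count >= ``min_mean`` across all samples,
    strictly longer than ``min_length`` (when set), and in the subfamily
    whitelist (when set; ``*`` wildcards allowed, e.g. ``L1PA*``).
    """
    keep = raw.mean(axis=1) >= min_mean
    if min_length is not None:
        if lengths is None:
            raise ValueError("length filter requested but no lengths provided")
        keep &= lengths.reindex(raw.index) > min_length
    if subfamilies is not None:
        if feature_subfamilies is None:
            raise ValueError("subfamily filter requested but no subfamilies provided")
        keep &= feature_subfamilies.reindex(raw.index).map(
            lambda s: isinstance(s, str) and _match_subfamily(s, subfamilies)
        )
    return ExpressedSet(
        feature_ids=tuple(raw.index[keep.fillna(False)]),
        min_mean_reads=min_mean,
        min_length=min_length,
        subfamilies=tuple(subfamilies) if subfamilies is not None else None,
    )


def millidiv_summary(loci, expressed: ExpressedSet) -> pd.DataFrame:
    """Per-subfamily arithmetic mean MilliDiv for all loci and for the
    expressed subset; subfamilies with no locus in a stratum get NaN there,
    empty subfamilies are omitted entirely."""
    expressed_ids = set(expressed.feature_ids)
    rows = {}
    for locus in loci:
        rows.setdefault(locus.subfamily, {"all": [], "expressed": []})
        rows[locus.subfamily]["all"].append(locus.milli_div)
        if locus.id in expressed_ids:
            rows[locus.subfamily]["expressed"].append(locus.milli_div)
    out = pd.DataFrame(
        {
            "subfamily": list(rows),
            "mean_millidiv_all": [float(np.mean(v["all"])) for v in rows.values()],
            "mean_millidiv_expressed": [
                float(np.mean(v["expressed"])) if v["expressed"] else np.nan
                for v in rows.values()
            ],
            "n_all": [len(v["all"]) for v in rows.values()],
            "n_expressed": [len(v["expressed"]) for v in rows.values()],
        }
    )
    return out.sort_values("subfamily").reset_index(drop=True)


# Warnings column value meaning "no warning" (IRFinder prints a dash; both the
# ASCII hyphen and the en-dash seen in text exports are accepted).
NO_WARNING = {"-", "–"}


def filter_retained_introns(records: pd.DataFrame) -> pd.DataFrame:
    """Retained introns: IRratio >= 0.1, IntronDepth >= 3 (both inclusive),
    no warnings, and no overlap with a known feature."""
    keep = (
        (records["IRratio"] >= 0.1)
        & (records["IntronDepth"] >= 3)
        & records["Warnings"].isin(NO_WARNING)
        & ~records["overlaps_known_feature"].astype(bool)
    )
    return records[keep].reset_index(drop=True)
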