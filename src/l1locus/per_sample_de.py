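"""Per-sample z-score differential expression without replicates.

Each sample is compared on its own against the control distribution: for a
case sample, z = (x − mean(controls)) / sd(controls) per feature, on
normalized linear-scale values.  Control samples are scored leave-one-out
against the remaining controls, so no sample is compared with itself.
Features with zero control variance are 'undefined' and never called DE.
|z| > 3 (strict) is the differential-expression rule; the net-upregulation
score of a sample is #(z > 3) − #(z < −3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

Z_THRESHOLD_DEFAULT = 3.0

CONTROL = "control"


def split_groups(samples: pd.DataFrame) -> tuple[list[str], list[str]]:
    """(controls, cases) sample ids from a sample sheet with a 'group' column."""
    controls = samples.loc[samples["group"] == CONTROL, "sample_id"].tolist()
    cases = samples.loc[samples["group"] != CONTROL, "sample_id"].tolist()
    return controls, cases


def per_sample_z(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    features=None,
    z_threshold: float = Z_THRESHOLD_DEFAULT,
    ddof: int = 1,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Long-format z table: one row per (feature, sample).

    Columns: feature, sample, z, log2fc, status.  ``status`` is ``up`` when
    z > threshold, ``down`` when z < −threshold, ``undefined`` when the
    control sd is 0, ``ns`` otherwise.  log2fc = log2((x+ε)/(ctrl_mean+ε)).
    ``features`` (an ExpressedSet or iterable of ids) restricts the universe.
    """
    controls, cases = split_groups(samples)
    if len(controls) < 3:
        raise ValueError(
            f"need >= 3 control samples for leave-one-out z-scores, got {len(controls)}"
        )
    if features is not None:
        ids = [f for f in norm.index if f in features]
        norm = norm.loc[ids]
    ctrl = norm[controls].to_numpy(dtype=float)
    n_ctrl = len(controls)

    frames = []

    def _score(sample_ids, means, sds, values):
        z = np.where(sds > 0, (values - means) / np.where(sds > 0, sds, 1.0), np.nan)
        log2fc = np.log2((values + pseudocount) / (means + pseudocount))
        for j, sid in enumerate(sample_ids):
            status = np.full(norm.shape[0], "ns", dtype=object)
            status[np.isnan(z[:, j])] = "undefined"
            status[np.nan_to_num(z[:, j]) > z_threshold] = "up"
            status[np.nan_to_num(z[:, j]) < -z_threshold] = "down"
            frames.append(
                pd.DataFrame(
                    {
                        "feature": norm.index,
                        "sample": sid,
                        "z": z[:, j],
                        "log2fc": log2fc[:, j],
                        "status": status,
                    }
                )
            )

    if cases:
        means = ctrl.mean(axis=1, keepdims=True)
        sds = ctrl.std(axis=1, ddof=ddof, keepdims=True)
        _score(cases, means, sds, norm[cases].to_numpy(dtype=float))

    # leave-one-out for each control sample
    for j, sid in enumerate(controls):
        rest = np.delete(ctrl, j, axis=1)
        means = rest.mean(axis=1, keepdims=True)
        sds = rest.std(axis=1, ddof=ddof, keepdims=True)
        _score([sid], means, sds, ctrl[:, [j]])

    out = pd.concat(frames, ignore_index=True)
    order = {s: i for i, s in enumerate(list(samples["sample_id"]))}
    return out.sort_values(
        ["sample", "feature"], key=lambda col: col.map(order) if col.name == "sample" else col
    ).reset_index(drop=True)


def net_upregulated(zt: pd.DataFrame, z_threshold: float = Z_THRESHOLD_DEFAULT) -> pd.DataFrame:
    """Per-sample n_up = #(z > thr), n_down = #(z < −thr), net = n_up − n_down.

    Undefined entries (NaN z) never count.
    """
    rows = []
    for sid, sub in zt.groupby("sample", sort=False):
        z = sub["z"].to_numpy(dtype=float)
        n_up = int(np.nansum(z > z_threshold))
        n_down = int(np.nansum(z < -z_threshold))
        rows.append({"sample": sid, "n_up": n_up, "n_down": n_down, "net": n_up - n_down})
    return pd.DataFrame(rows, columns=["sample", "n_up", "n_down", "net"])


def log2_fold_change(
    norm: pd.DataFrame, samples: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Feature × sample log2((x+ε)/(control mean+ε)); controls leave-one-out."""
    controls, cases = split_groups(samples)
    ctrl = norm[controls].to_numpy(dtype=float)
    out = {}
    if cases:
        mean = ctrl.mean(axis=1)
        for sid in cases:
            out[sid] = np.log2(
                (norm[sid].to_numpy(dtype=float) + pseudocount) / (mean + pseudocount)
            )
    for j, sid in enumerate(controls):
        mean = np.delete(ctrl, j, axis=1).mean(axis=1)
        out[sid] = np.log2((ctrl[:, j] + pseudocount) / (mean + pseudocount))
    cols = [s for s in samples["sample_id"] if s in out]
    return pd.DataFrame(out, index=norm.index)[cols]


def de_gene_counts(zt: pd.DataFrame, z_threshold: float = Z_THRESHOLD_DEFAULT) -> pd.Series:
    """Per-sample tally of |z| > threshold features (undefined excluded)."""
    if zt.empty:
        return pd.Series(dtype=int, name="n_de")
    counts = zt.groupby("sample", sort=False)["z"].apply(
        lambda z: int(np.nansum(np.abs(z.to_numpy(dtype=float)) > z_threshold))
    )
    counts.name = "n_de"
    return counts


def expected_false_positive_count(n_features: int, n_controls: int,
                                  z_threshold: float = Z_THRESHOLD_DEFAULT) -> float:
    """Expected null |z|>thr calls per case sample under a Gaussian model:
    (x − x̄)/s with n controls is t-distributed with n−1 df after the
    √(1+1/n) inflation.  Annotates reports; no correction is applied."""
    from scipy import stats

    t = z_threshold / np.sqrt(1.0 + 1.0 / n_controls)
    return float(n_features * 2.0 * stats.t.sf(t, df=n_controls - 1))
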