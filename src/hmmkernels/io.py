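"""Data ingestion, model persistence and the end-to-end pipeline.

Timeseries are delimited-text matrices (rows = timepoints, columns =
channels) or ``.npy`` arrays; a manifest table lists subject_id, file path,
optional family_id and optional per-session row ranges.  Fitted models and
kernels are written as ``.npz`` containers / delimited text with enough
metadata (config hash, seed) to reproduce a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hmm import HMMParams, dual_estimate, fit_group_hmm, normalise_timeseries

logger = logging.getLogger(__name__)

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "load_manifest",
    "load_timeseries",
    "save_model",
    "load_model",
    "save_kernel",
    "load_kernel",
    "load_config",
    "config_hash",
    "run_pipeline",
]


def read_timeseries(path) -> np.ndarray:
    """Read one subject's T x M matrix from text (or .npy)."""
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    return np.loadtxt(path, delimiter=None if path.suffix == ".txt" else ",", ndmin=2)


def write_timeseries(path, x: np.ndarray) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, x)
    else:
        np.savetxt(path, x, delimiter="," if path.suffix == ".csv" else " ",
                   fmt="%.17g")


def _parse_sessions(spec) -> list | None:
    """Parse 'a:b;c:d' session row-ranges into slice lengths."""
    if spec is None or (isinstance(spec, float) and np.isnan(spec)) or spec == "":
        return None
    out = []
    for part in str(spec).split(";"):
        a, b = part.split(":")
        out.append((int(a), int(b)))
    return out


def load_manifest(path) -> pd.DataFrame:
    """Read the subject manifest (CSV/TSV: subject_id, file[, family_id, sessions])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t" if path.suffix in (".tsv", ".txt") else ",")
    if "subject_id" not in df or "file" not in df:
        raise ValueError("manifest needs subject_id and file columns")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id(s) in manifest: {dup}")
    if "family_id" not in df:
        df["family_id"] = df["subject_id"]
    return df


def load_timeseries(manifest: pd.DataFrame, root=None, normalise: bool = True):
    """Load all subjects' timeseries listed in a manifest.

    Returns (series, lengths, subject_ids); ``lengths`` holds per-subject
    session lengths (None when a subject has a single session).  All
    subjects must share the channel count.
    """
    series, lengths, ids = [], [], []
    for _, row in manifest.iterrows():
        p = Path(row["file"])
        if root is not None and not p.is_absolute():
            p = Path(root) / p
        x = read_timeseries(p)
        sess = _parse_sessions(row.get("sessions"))
        if sess is not None:
            x = np.vstack([x[a:b] for a, b in sess])
            lengths.append([b - a for a, b in sess])
        else:
            lengths.append(None)
        if normalise:
            x = normalise_timeseries(x)
        series.append(x)
        ids.append(row["subject_id"])
    Ms = {x.shape[1] for x in series}
    if len(Ms) > 1:
        offenders = [(i, x.shape[1]) for i, x in zip(ids, series)]
        raise ValueError(f"channel counts differ across subjects: {offenders}")
    return series, lengths, ids


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def save_model(path, params: HMMParams, config: dict | None = None, seed=None) -> None:
    """Persist theta = [pi, A, mu, sigma] plus K, M, config and seed."""
    config = config or {}
    np.savez(
        path, pi=params.pi, A=params.A, mu=params.mu, sigma=params.sigma,
        K=params.K, M=params.M, config=json.dumps(config, default=str),
        seed=-1 if seed is None else seed, config_hash=config_hash(config),
    )


def load_model(path):
    """Load a model saved by :func:`save_model`; returns (params, meta)."""
    with np.load(path, allow_pickle=False) as z:
        params = HMMParams(z["pi"], z["A"], z["mu"], z["sigma"])
        meta = {"K": int(z["K"]), "M": int(z["M"]),
                "config": json.loads(str(z["config"])),
                "seed": int(z["seed"]), "config_hash": str(z["config_hash"])}
    return params, meta


def save_kernel(path, kernel: np.ndarray, subject_ids) -> None:
    """Square kernel as delimited text with a subject-ID header row/column."""
    df = pd.DataFrame(kernel, index=subject_ids, columns=subject_ids)
    df.to_csv(path)


def load_kernel(path):
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.index)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "K": 6,
    "zero_mean": False,
    "kernel": "fisher",        # fisher | naive | naive_norm | kl
    "embed": "linear",          # linear | gaussian
    "features": "all",          # all | state | transition | pca
    "training_scheme": "together",  # together | separate
    "k_outer": 10,
    "k_inner": 10,
    "n_repeats": 1,
    "seed": 0,
    "confounds": [],
    "targets": None,             # None = all non-id, non-confound columns
    "n_restarts": 3,
}

_FEATURE_MODES = {"all": None, "state": "state_only",
                  "transition": "transition_only", "pca": "pca_state"}


def _build_feature_matrix(group, series, kernel_kind, feature_mode, train_rows=None):
    from .kernels import (fisher_scores, naive_features, normalise_features,
                          subset_features)

    if kernel_kind == "fisher":
        fs = fisher_scores(group, series)
    else:
        params = [dual_estimate(group, x) for x in series]
        fs = naive_features(params)
        if kernel_kind == "naive_norm":
            fs = normalise_features(fs, stats_from=train_rows)
    if feature_mode:
        fs = subset_features(fs, feature_mode, train_rows=train_rows)
    return fs


def make_kernel(group, series, kernel_kind: str, embed: str = "linear",
                feature_mode: str | None = None, tau: float | None = None,
                train_rows=None) -> np.ndarray:
    """One kernel matrix from a fitted group model and subject timeseries."""
    from .kernels import gaussian_kernel, kl_kernel, linear_kernel

    if kernel_kind == "kl":
        params = [dual_estimate(group, x) for x in series]
        _, K = kl_kernel(params, tau=tau if tau is not None else 1.0,
                         train_rows=train_rows)
        return K
    fs = _build_feature_matrix(group, series, kernel_kind, feature_mode, train_rows)
    if embed == "linear":
        return linear_kernel(fs)
    return gaussian_kernel(fs, tau if tau is not None else 1.0, train_rows=train_rows)


def run_pipeline(config: dict, manifest=None, subject_table=None, out_dir=None):
    """Concatenate -> group HMM -> dual estimation -> kernel -> nested-CV KRR.

    ``manifest`` is a manifest DataFrame or path; ``subject_table`` a
    DataFrame or path with subject_id, family_id, confound and target
    columns.  Under ``training_scheme='separate'`` the group HMM (and hence
    the kernel) is refit per outer fold on training subjects only.

    Returns a dict with the group model, kernels and a
    :class:`~hmmkernels.prediction.PredictionResult` per target; artifacts
    are written to ``out_dir`` when given, each tagged with the config hash.
    """
    from .prediction import (HyperparamGrid, make_cv_scheme, nested_cv_predict)

    cfg = {**_DEFAULT_CONFIG, **(config or {})}
    chash = config_hash(cfg)
    t0 = time.time()
    if isinstance(manifest, (str, Path)):
        manifest = load_manifest(manifest)
    if isinstance(subject_table, (str, Path)):
        p = Path(subject_table)
        subject_table = pd.read_csv(p, sep="\t" if p.suffix in (".tsv", ".txt") else ",")

    series, lengths, ids = load_timeseries(manifest)
    logger.info("stage load: %d subjects in %.1fs", len(series), time.time() - t0)

    table = subject_table.set_index("subject_id").loc[ids].reset_index()
    groups = table["family_id"].to_numpy() if "family_id" in table else None
    scheme = make_cv_scheme(len(series), groups=groups, k_outer=cfg["k_outer"],
                            k_inner=cfg["k_inner"], n_repeats=cfg["n_repeats"],
                            seed=cfg["seed"])

    feature_mode = _FEATURE_MODES[cfg["features"]]
    embed = cfg["embed"]
    kernel_kind = cfg["kernel"]

    results, bundle = {}, {}
    if cfg["training_scheme"] == "together":
        t1 = time.time()
        group, history = fit_group_hmm(series, cfg["K"], lengths=lengths,
                                       zero_mean=cfg["zero_mean"],
                                       n_restarts=cfg["n_restarts"],
                                       random_state=cfg["seed"])
        logger.info("stage group-hmm: loglik %.1f in %.1fs", history[-1], time.time() - t1)
        bundle["group_model"] = group

        def builder(tau, train_idx):
            return make_kernel(group, series, kernel_kind, embed, feature_mode,
                               tau=tau, train_rows=train_idx)
    else:
        def builder(tau, train_idx, _cache={}):
            key = tuple(np.sort(np.asarray(train_idx)))
            if key not in _cache:
                sub = [series[i] for i in train_idx]
                g, _ = fit_group_hmm(sub, cfg["K"], zero_mean=cfg["zero_mean"],
                                     n_restarts=cfg["n_restarts"],
                                     random_state=cfg["seed"])
                _cache[key] = g
            return make_kernel(_cache[key], series, kernel_kind, embed,
                               feature_mode, tau=tau, train_rows=train_idx)

    builder.linear = embed == "linear" and kernel_kind != "kl"
    id_cols = {"subject_id", "family_id"}
    confounds = table[cfg["confounds"]].to_numpy(dtype=float) if cfg["confounds"] else None
    target_cols = cfg["targets"] or [c for c in table.columns
                                     if c not in id_cols | set(cfg["confounds"])]
    for col in target_cols:
        y = table[col].to_numpy(dtype=float)
        keep = np.isfinite(y)
        if not keep.all():
            # listwise removal per variable: rebuild the scheme on kept rows
            kidx = np.where(keep)[0]
            sub_scheme = make_cv_scheme(
                kidx.size, groups=None if groups is None else groups[kidx],
                k_outer=cfg["k_outer"], k_inner=cfg["k_inner"],
                n_repeats=cfg["n_repeats"], seed=cfg["seed"])

            def sub_builder(tau, train_idx, _kidx=kidx):
                full = builder(tau, _kidx[train_idx])
                return full[np.ix_(_kidx, _kidx)]

            sub_builder.linear = builder.linear

            res = nested_cv_predict(sub_builder, y[kidx],
                                    None if confounds is None else confounds[kidx],
                                    sub_scheme, HyperparamGrid(),
                                    variable_name=col)
        else:
            res = nested_cv_predict(builder, y, confounds, scheme,
                                    HyperparamGrid(), variable_name=col)
        res.table["config_hash"] = chash
        results[col] = res
        logger.info("stage predict[%s]: mean r %.3f", col, res.mean_r())

    bundle["results"] = results
    bundle["config"] = cfg
    bundle["config_hash"] = chash
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump({**cfg, "config_hash": chash}, fh)
        if "group_model" in bundle:
            save_model(out / "group_model.npz", bundle["group_model"], cfg, cfg["seed"])
        pd.concat([r.table for r in results.values()]).to_csv(
            out / "results.csv", index=False)
    return bundle
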