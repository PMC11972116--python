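"""Wavelet-comparison harness: k-fold CV of the model per mother wavelet.

For each registered wavelet the same Conv+BiGRU+Wav-KAN model is trained
and evaluated on every fold of a protein-grouped CV plan; the table
reports mean and standard deviation of each metric per wavelet.  A
max-scaled companion table (every column divided by its maximum, so the
best wavelet per metric scores exactly 1) supports radar-style visual
comparison.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from phoskan.errors import PhosKANError
from phoskan.metrics import compute_metrics
from phoskan.nn.model import ModelConfig, PhosKANModel
from phoskan.nn.wavelets import get_wavelet
from phoskan.train import FoldPlan, TrainConfig, WindowDataset, train

_METRIC_COLS = ["MCC", "PRE", "REC", "SP", "F1", "F1_weighted", "AUPR",
                "AUROC"]


def evaluate_wavelets(
    dataset: WindowDataset,
    wavelet_names: Sequence[str],
    cv_plan: FoldPlan,
    model_config: ModelConfig,
    train_config: Optional[TrainConfig] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """CV mean +/- sd of every metric for each wavelet, plus the
    max-scaled table used for radar plots.

    Returns ``(summary, scaled)``: ``summary`` has one row per
    (wavelet, metric) with mean and sd columns; ``scaled`` has one row
    per wavelet with each mean-metric column divided by that column's
    maximum over wavelets.
    """
    for name in wavelet_names:
        get_wavelet(name)  # raises on unknown wavelets up front
    train_config = train_config or TrainConfig()

    per_wavelet: Dict[str, List[dict]] = {}
    for name in wavelet_names:
        fold_metrics: List[dict] = []
        for fold in range(cv_plan.k):
            tr_idx, val_idx = cv_plan.fold_indices(dataset.protein_ids, fold)
            if len(val_idx) == 0:
                continue
            tr, val = dataset.subset(tr_idx), dataset.subset(val_idx)
            cfg = replace(model_config, wavelet=get_wavelet(name).name)
            model = PhosKANModel(cfg)
            train(model, tr, val, train_config)
            probs = model.predict_proba(val.windows)
            report = compute_metrics(val.labels, probs)
            fold_metrics.append(report.as_dict())
        if not fold_metrics:
            raise PhosKANError("CV plan produced no non-empty folds")
        per_wavelet[name] = fold_metrics

    rows = []
    for name, folds in per_wavelet.items():
        for metric in _METRIC_COLS:
            vals = [f[metric] for f in folds if f[metric] is not None]
            rows.append({
                "wavelet": name,
                "metric": metric,
                "mean": float(np.mean(vals)) if vals else np.nan,
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "n_folds": len(vals),
            })
    summary = pd.DataFrame(rows)

    means = summary.pivot(index="wavelet", columns="metric", values="mean")
    means = means[_METRIC_COLS]
    scaled = means / means.max(axis=0)
    return summary, scaled
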