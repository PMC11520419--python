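"""Hyperparameter sensitivity harness.

Given one completed alignment, the sweep re-solves only the matching and
integration stage for a grid of values of one schedule constant — the noise
floor ε, the marker-evidence weight β₂, or the capacity t — and scores each
setting by the silhouette-based integration F1 on the integrated embedding
(batches should mix, cell types should separate).  Because clustering, CCA
and marker detection are shared across the grid, the sweep isolates the
constant under study.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import silhouette_f1
from .search import AlignmentResult, rematch


def sweep_value(result: AlignmentResult, batch_labels, type_labels,
                **override) -> dict:
    """One sweep point: re-match with ``override`` and score integration."""
    res = rematch(result, **override)
    s_batch, s_type, f1 = silhouette_f1(res.integrated.e, batch_labels,
                                        type_labels)
    return {"s_batch": s_batch, "s_celltype": s_type, "f1_sil": f1,
            "n_matches": res.match.n_matches}


def sensitivity_sweep(
    result: AlignmentResult,
    batch_labels,
    type_labels,
    epsilons: Optional[Sequence[float]] = None,
    beta2s: Optional[Sequence[float]] = None,
    ts: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Sweep ε, β₂ and/or t around a fitted alignment.

    Returns one row per (parameter, value) with the integration silhouettes
    and F1; the fitted values themselves are included for reference.
    """
    batch_labels = np.asarray(batch_labels)
    type_labels = np.asarray(type_labels)
    rows = []
    if epsilons is None and beta2s is None and ts is None:
        epsilons = [result.scores.epsilon * f for f in (0.8, 0.9, 1.0, 1.1)]
        beta2s = [result.scores.beta2 * f for f in (0.5, 1.0, 1.5, 2.0)]
        ts = [1, 2, 3]
    for eps in epsilons or []:
        rec = sweep_value(result, batch_labels, type_labels, epsilon=eps)
        rows.append({"parameter": "epsilon", "value": eps, **rec})
    for b2 in beta2s or []:
        rec = sweep_value(result, batch_labels, type_labels, beta2=b2)
        rows.append({"parameter": "beta2", "value": b2, **rec})
    for t in ts or []:
        rec = sweep_value(result, batch_labels, type_labels, t=int(t))
        rows.append({"parameter": "t", "value": t, **rec})
    return pd.DataFrame(rows)
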