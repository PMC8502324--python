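"""Variable importance and direction of effect from trained weights.

Two complementary readings of a single-hidden-layer network's synapses:

* **Garson index** — the percentage contribution of each input, computed
  from absolute products of input→hidden and hidden→output weights,
  normalized within each hidden neuron and then across inputs so the
  contributions sum to 100%.
* **Sign of contribution** — the sign of the summed connection-weight
  products Σ_j w_ij·v_j (Olden-style), indicating whether the input pushes
  the predicted probability of the outcome up or down.

Each dummy column is scored separately, so e.g. afternoon and night
admissions each get their own contribution and sign.
"""

from __future__ import annotations

import csv

import numpy as np

from losnet.mlp import NetworkParameters


def garson(params: NetworkParameters) -> np.ndarray:
    """Garson percentage contribution of each input (sums to 100).

    c_ij = |w_ij|·|v_j| is shared among inputs within hidden neuron j
    (r_ij = c_ij / Σ_k c_kj; neurons with all-zero inflow are skipped), then
    summed over neurons and rescaled to percent.  The output bias carries no
    input information and is excluded.
    """
    C = np.abs(params.W_in) * np.abs(params.w_out)[:, None]   # (hidden, inputs)
    col_tot = C.sum(axis=1)                                    # per hidden neuron
    keep = col_tot > 0
    if not keep.any():
        raise ValueError("all weights are zero; importance undefined")
    R = C[keep] / col_tot[keep, None]
    S = R.sum(axis=0)
    return 100.0 * S / S.sum()


def contribution_signs(params: NetworkParameters) -> list[str]:
    """'positive' / 'negative' / 'zero' per input, from Σ_j w_ij·v_j."""
    s = params.W_in.T @ params.w_out   # (inputs,)
    return ["positive" if v > 0 else "negative" if v < 0 else "zero" for v in s]


def importance_report(
    params: NetworkParameters, column_names: list[str]
) -> list[dict]:
    """Per-input rows: column name, Garson percent, sign; Garson-descending."""
    if len(column_names) != params.n_inputs:
        raise ValueError(
            f"{len(column_names)} column names for a {params.n_inputs}-input network"
        )
    pct = garson(params)
    signs = contribution_signs(params)
    rows = [
        {"column": c, "garson_pct": float(g), "sign": s}
        for c, g, s in zip(column_names, pct, signs)
    ]
    rows.sort(key=lambda r: -r["garson_pct"])
    return rows


def write_importance_csv(rows: list[dict], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=["column", "garson_pct", "sign"])
        writer.writeheader()
        writer.writerows(rows)
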