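#!/usr/bin/env python
"""Compare the quadratic model and the network surrogate on six metrics.

Computes R^2, MSE, RMSE, both SSE conventions, AIC, and AAD for (a) the
reduced quadratic, (b) the full quadratic, and (c) the reference network,
all over the 30 design runs, and prints the per-metric winners.
"""

import json
from pathlib import Path

from extropt import ann, metrics, rsm
from extropt.design import load_table1

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    table = load_table1()
    y = table.response

    full = rsm.fit_quadratic(table)
    reduced = rsm.reduce_model(full, table, alpha=0.05)
    weights, scalers = ann.load_fixture_weights()

    candidates = {
        "rsm_reduced": (reduced.predict(table.coded), reduced.n_active),
        "rsm_full": (full.predict(table.coded), full.n_active),
        "ann_reference": (ann.forward(weights, scalers, table.actual),
                          weights.n_parameters),
    }
    all_metrics = {
        name: metrics.compute_metrics(pred, y, p=p)
        for name, (pred, p) in candidates.items()
    }
    for name, m in all_metrics.items():
        print(f"{name:14s} " + json.dumps(
            {k: round(v, 4) for k, v in m.to_dict().items()}))

    cmp = metrics.compare_models(
        all_metrics["ann_reference"], all_metrics["rsm_reduced"], "ann", "rsm"
    )
    print(f"\nper-metric winners: {cmp['winners']}")
    print(f"verdict: {cmp['verdict']} (wins {cmp['wins']})")

    (OUT / "model_comparison.json").write_text(
        json.dumps(
            {name: m.to_dict() for name, m in all_metrics.items()}
            | {"comparison": cmp},
            indent=1,
        )
    )
    print(f"wrote {OUT/'model_comparison.json'}")


if __name__ == "__main__":
    main()
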