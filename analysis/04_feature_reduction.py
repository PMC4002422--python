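"""Feature reduction on the two-class phantom data.

Runs the nested sequential-forward-search with the Bernoulli-error BIC on the
feature table written by 02_two_class_separability.py (regenerating it if
absent), reports the per-fold selected sets and their union, and compares CV
accuracy on the full 65 features vs the reduced union set.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from speckletex.features import FEATURE_REGISTRY
from speckletex.model import cross_validate
from speckletex.reduction import select_features_nested

ROOT = Path(__file__).resolve().parents[1]
TWO_CLASS = ROOT / "results" / "two_class" / "features.csv"
OUT = ROOT / "results" / "reduction"


def main(seed: int = 7) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    if not TWO_CLASS.exists():
        from speckletex.pipeline import ExperimentConfig, run_experiment

        run_experiment(
            ExperimentConfig(design="two_class_24h", n_per_group=20, n_subsets=4, seed=seed),
            TWO_CLASS.parent,
        )
    df = pd.read_csv(TWO_CLASS)
    res = select_features_nested(df, max_features=10, seed=seed, feature_names=FEATURE_REGISTRY)
    print("per-fold selected sets:")
    for fold, feats in res.per_fold_sets.items():
        print(f"  {fold}: {feats}")
    print(f"union ({len(res.union_set)} features): {res.union_set}")
    full = cross_validate(df, FEATURE_REGISTRY, k_candidates=(1,), seed=seed)
    red = cross_validate(df, res.union_set, k_candidates=(1,), seed=seed)
    print(f"accuracy, all 65 features: {full.overall_accuracy:.3f}")
    print(f"accuracy, union set:       {red.overall_accuracy:.3f}")
    (OUT / "selection.json").write_text(
        json.dumps(
            {
                "per_fold_sets": res.per_fold_sets,
                "union_set": res.union_set,
                "bic_curve": res.bic_curve,
                "error_curve": res.error_curve,
                "accuracy_full": full.overall_accuracy,
                "accuracy_union": red.overall_accuracy,
            },
            indent=1,
        )
    )


if __name__ == "__main__":
    main()
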