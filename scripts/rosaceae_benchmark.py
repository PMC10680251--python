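#!/usr/bin/env python
"""Optional benchmark on the deposited Rosaceae 6mA datasets (needs network).

Downloads the Rosaceae training and testing FASTA pairs from the published
repository (https://github.com/Xiaohong-source/6mA-stackingCV), verifies
the documented record counts (29,237/29,433 training; 7,298/7,300 testing;
all 41 nt), trains the default model (one-hot + EIIP features; XGBoost,
gradient boosting and LightGBM first layer; SVM second layer; K = 5), and
prints SN/SP/ACC/MCC/AUC on the independent test set.

This is an aspiration check, not a gate: published numbers depend on
hyperparameters and seeds the original work does not state, so agreement
within roughly ±0.02 ACC is the realistic expectation.

Usage::

    python scripts/rosaceae_benchmark.py --work-dir scratch/rosaceae --seed 0
"""

import argparse
import json
import urllib.request
from pathlib import Path

from sixmastack.encoders import EncoderSpec
from sixmastack.evaluation import evaluate
from sixmastack.sequence_io import load_labeled
from sixmastack.stacking import (
    fit_stacking,
    paper_default_base_specs,
    paper_default_final_spec,
)

BASE_URL = (
    "https://raw.githubusercontent.com/Xiaohong-source/6mA-stackingCV/main/dataset"
)
FILES = {
    "train_pos.fasta": f"{BASE_URL}/Rosaceae_train_pos.fasta",
    "train_neg.fasta": f"{BASE_URL}/Rosaceae_train_neg.fasta",
    "test_pos.fasta": f"{BASE_URL}/Rosaceae_test_pos.fasta",
    "test_neg.fasta": f"{BASE_URL}/Rosaceae_test_neg.fasta",
}
EXPECTED_COUNTS = {
    "train_pos.fasta": 29_237,
    "train_neg.fasta": 29_433,
    "test_pos.fasta": 7_298,
    "test_neg.fasta": 7_300,
}


def fetch(work_dir: Path) -> None:
    work_dir.mkdir(parents=True, exist_ok=True)
    for name, url in FILES.items():
        target = work_dir / name
        if target.exists():
            continue
        print(f"downloading {url}")
        urllib.request.urlretrieve(url, target)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--work-dir", type=Path, default=Path("scratch/rosaceae"))
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    fetch(args.work_dir)
    train = load_labeled(
        args.work_dir / "train_pos.fasta",
        args.work_dir / "train_neg.fasta",
        expected_length=41,
    )
    test = load_labeled(
        args.work_dir / "test_pos.fasta",
        args.work_dir / "test_neg.fasta",
        expected_length=41,
    )
    for name, expected in EXPECTED_COUNTS.items():
        count = sum(
            1 for line in (args.work_dir / name).read_text().splitlines()
            if line.startswith(">")
        )
        status = "ok" if count == expected else f"MISMATCH (expected {expected})"
        print(f"{name}: {count} records {status}")

    model = fit_stacking(
        train,
        [EncoderSpec("onehot"), EncoderSpec("eiip")],
        paper_default_base_specs(args.seed),
        paper_default_final_spec(args.seed),
        K=5,
        seed=args.seed,
    )
    report = evaluate(model, test)
    print(json.dumps(report.to_dict(), indent=2))


if __name__ == "__main__":
    main()
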