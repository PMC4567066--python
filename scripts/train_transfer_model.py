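#!/usr/bin/env python
"""Regenerate the packaged transfer-classifier fixture.

Usage: python scripts/train_transfer_model.py [--seed 20150911] [--n-draws 60]
       [--out src/tolsense/data/transfer_svm_v1.json]

Also prints hold-out accuracy on a freshly drawn synthetic set.
"""

import argparse
from pathlib import Path

import numpy as np

from tolsense.detectors import TransferModel
from tolsense.training import make_transfer_training_set


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20150911)
    ap.add_argument("--n-draws", type=int, default=60)
    ap.add_argument("--out", type=Path,
                    default=Path("src/tolsense/data/transfer_svm_v1.json"))
    args = ap.parse_args()

    X, y = make_transfer_training_set(args.n_draws, args.seed)
    model = TransferModel().fit(X, y, seed=args.seed)
    model.save(args.out)
    print(f"trained on {len(y)} windows "
          f"({dict(zip(*np.unique(y.astype(str), return_counts=True)))})")

    Xh, yh = make_transfer_training_set(20, args.seed + 1)
    acc = float(np.mean(model.predict(Xh) == yh))
    print(f"hold-out accuracy: {acc:.3f} on {len(yh)} windows")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
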