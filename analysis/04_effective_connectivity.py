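"""Effective connectivity between the DMN and ON via euSEM.

Group-iterative structure search over contemporaneous, lagged, exogenous
and bilinear candidate paths, then extraction of the per-subject DMN->ON
coefficient, residualized on age.
"""

import json
import os

import pandas as pd

from common import driver_config
from olfnet.pipeline import stage_eusem


def main():
    cfg = driver_config(__doc__)
    stage_eusem(cfg)
    edir = os.path.join(cfg.out_dir, "derivatives", "eusem")
    with open(os.path.join(edir, "group_structure.json")) as fh:
        structure = json.load(fh)
    print("selected structure:")
    for path in structure["paths"]:
        print(f"  {path}")
    for entry in structure["search_log"]:
        print(f"  [{entry['action']}] {entry['path']}")
    ec = pd.read_csv(os.path.join(edir, "ec_dmn_to_on.csv"))
    print(f"DMN->ON EC: mean {ec.ec.mean():.3f}, sd {ec.ec.std():.3f}, "
          f"n = {len(ec)}")


if __name__ == "__main__":
    main()
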