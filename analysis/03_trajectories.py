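#!/usr/bin/env python
"""Call salt-stress differential expression and group trajectories.

Each treated time point (1/6/24/48 h) is tested against 0 h; genes
differentially expressed at >= 2 time points are salt-responsive and fall
into one of four trajectory groups. Writes de_calls.tsv and
trajectories.tsv under results/analysis/.
"""

import os

from saltnac import expression as ex
from saltnac import io as snio

HERE = os.path.dirname(os.path.abspath(__file__))
RES = os.path.join(HERE, "..", "results", "analysis")


def main() -> None:
    fpkm = snio.read_expression_tsv(f"{RES}/sim/fpkm.tsv")
    de = ex.de_scan(fpkm)
    traj = ex.classify_trajectories(de)
    snio.write_tsv(de, f"{RES}/de_calls.tsv")
    snio.write_tsv(traj, f"{RES}/trajectories.tsv")
    n_resp = int(traj.salt_responsive.sum())
    counts = traj.group.value_counts().sort_index()
    print(f"{n_resp} of {len(traj)} genes salt-responsive "
          f"(DE at >= 2 time points)")
    for grp, n in counts.items():
        print(f"  group {grp}: {n} genes")


if __name__ == "__main__":
    main()
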