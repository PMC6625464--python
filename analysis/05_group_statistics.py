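"""Group statistics: score ANOVAs, correlations, and the EC-UPSIT analysis.

Runs the full analysis grid on the retained cohort - behavioral score
ANOVAs, UPSIT-cognition correlations, beta and volume associations, and
the MCI-only EC-UPSIT correlation (UPSIT > 20) with the UPSIT x DRS-memory
ANCOVA - and writes <out>/derivatives/stats/report.json.
"""

from common import driver_config
from olfnet.pipeline import stage_stats


def main():
    cfg = driver_config(__doc__)
    report = stage_stats(cfg)
    for score, res in report["score_anovas"].items():
        if res is not None:
            print(f"ANOVA {score:>10}: F = {res.f:6.2f}, p = {res.p:.2e}")
    for name, corr in report["correlations"].items():
        if corr is not None:
            print(f"r({name}) = {corr.r:+.3f}, p = {corr.p:.4f}")
    ec = report.get("ec", {})
    if ec.get("ec_vs_upsit_mci") is not None:
        r = ec["ec_vs_upsit_mci"]
        print(f"EC vs UPSIT (MCI, UPSIT>20, n={r.n}): "
              f"r = {r.r:.3f}, p = {r.p:.4f}")
    if ec.get("ancova") is not None:
        p = ec["ancova"].table.loc["upsit:drs_memory", "p"]
        print(f"UPSIT x DRS-memory interaction on EC: p = {p:.4f}")
    for line in report["log"]:
        print(f"  note: {line}")


if __name__ == "__main__":
    main()
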