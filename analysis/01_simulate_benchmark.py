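"""Generate the synthetic RT benchmark: library, external methods, query ions.

Writes the library as a fingerprint CSV, each external chromatographic
method's anchor table as a PredRet-style CSV, the query-ion tables, and the
generator ground truth as JSON, under results/data/. Every downstream script
regenerates the same objects deterministically from the same seed through
the package, so this script's outputs are a record (and an I/O round-trip
check), not a dependency.
"""

import argparse
import json
from pathlib import Path

from rtpred import molecules, synthetic_data as synth
from rtpred.annotate import write_query_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/data")
    args = ap.parse_args()
    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    cfg = synth.GeneratorConfig(seed=args.seed)
    records, truth = synth.gen_library(cfg)
    molecules.write_fp_csv(records, out / "library_fp.csv")
    truth.to_json(out / "library_truth.json")
    print(f"library: {len(records)} molecules, {cfg.n_bits}-bit fingerprints")
    print(f"  non-retained: {int(truth.nonretained.sum())} "
          f"(band {cfg.nonretained_range[0]:.0f}-{cfg.nonretained_range[1]:.0f} s, "
          f"retained start >= {truth.rt_latent[~truth.nonretained].min():.0f} s)")

    ecm_specs = {
        "ecm_long": synth.EcmConfig(length_s=1600.0, seed=args.seed + 1),
        "ecm_short": synth.EcmConfig(length_s=280.0, seed=args.seed + 2),
    }
    summary = {}
    for name, ecfg in ecm_specs.items():
        ecm = synth.gen_ecm(records, truth, ecfg)
        synth.write_anchor_csv(ecm, out / f"{name}_anchors.csv")
        ecm.table.to_csv(out / f"{name}_rt.csv", index=False)
        queries = synth.gen_query_ions(ecm, records, seed=args.seed + 3)
        write_query_csv(queries, out / f"{name}_queries.csv")
        summary[name] = {
            "n_molecules": len(ecm.table),
            "length_s": ecfg.length_s,
            "noise_sd_s": ecfg.effective_noise_sd,
            "n_anchors": len(ecm.anchor_ids),
            "n_queries": len(queries),
        }
        print(f"{name}: {len(ecm.table)} molecules on a {ecfg.length_s:.0f} s method, "
              f"{len(ecm.anchor_ids)} identified anchors, {len(queries)} query ions")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    # round-trip check: the CSV dialect we write is the one we read
    reread = molecules.read_molecules(str(out / "library_fp.csv"), "fp_csv")
    assert len(reread.records) == len(records) and reread.n_failed == 0
    print("fingerprint CSV round-trip: ok")


if __name__ == "__main__":
    main()
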