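"""Generate the synthetic study inputs: reference matures, an EST set with
planted homologs (half of them full hairpin cassettes), a transcriptome
with planted complementary sites, and a scale-free interaction set."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from cacmir.io_formats import write_fasta, write_report


def main() -> None:
    out = common.RESULTS / "simdata"
    out.mkdir(parents=True, exist_ok=True)

    refs = common.reference_mirnas()
    ests, est_truth = common.est_set()
    txs, site_truth = common.transcriptome(refs)
    idata, net_truth = common.interactions()

    write_fasta(refs, out / "refs.fasta")
    write_fasta(ests, out / "ests.fasta")
    write_fasta(txs, out / "transcripts.fasta")
    write_report(
        [dict(zip(("est_id", "ref_id", "pos", "mismatches"), t))
         for t in est_truth.planted_homologs],
        out / "truth_homologs.tsv",
        columns=["est_id", "ref_id", "pos", "mismatches"],
    )
    write_report(
        [dict(zip(("mirna_id", "transcript_id", "pos", "expectation"), t))
         for t in site_truth.planted_sites],
        out / "truth_sites.tsv",
        columns=["mirna_id", "transcript_id", "pos", "expectation"],
    )
    write_report(
        [{"protein_a": a, "protein_b": b} for a, b in idata.binary_pairs],
        out / "binary.tsv",
        columns=["protein_a", "protein_b"],
    )
    write_report(
        [{"complex_id": f"CPX{i:02d}", "protein": p}
         for i, cx in enumerate(idata.complexes) for p in cx],
        out / "complexes.tsv",
        columns=["complex_id", "protein"],
    )

    print(f"{len(refs)} reference matures, {len(ests)} ESTs "
          f"({len(est_truth.planted_homologs)} planted homologs, "
          f"{len(est_truth.planted_hairpin_ests)} as full hairpin cassettes).")
    print(f"{len(txs)} transcripts with {len(site_truth.planted_sites)} planted "
          f"target sites; interaction set: {len(idata.binary_pairs)} binary pairs, "
          f"{len(idata.complexes)} complexes, planted hub {net_truth.planted_hub_ids[0]}.")
    print(f"wrote inputs to {out}")


if __name__ == "__main__":
    main()
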