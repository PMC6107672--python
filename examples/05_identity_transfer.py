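"""Transfer LC-MS/MS peptide identities onto imaging m/z values.

Converts each marker ion to its neutral mass (singly protonated MALDI
peptide), matches it against an identification table within 0.9 Da, and
applies the two-peptide protein acceptance rule. The printed report carries
the mass deltas in Da and ppm.
"""

from msiregio import build_report, match_ims_to_lcms, monoisotopic_mass, \
    neutral_to_mz
from msiregio.refdata import REFERENCE_PEPTIDES
from msiregio.synth import make_id_table

import pandas as pd

# identification table: curated reference peptides at 5 ppm mass error,
# one accession per protein so the two-peptide rule can group them
rows = [(f"SYN_{p.gene}", p.gene, p.description, p.sequence)
        for p in REFERENCE_PEPTIDES]
id_table = make_id_table(rows, mass_error_sd_ppm=5.0, seed=3)

# imaging markers: the singly protonated ions of four of those peptides;
# Hspa8 contributes two, Ca3 and Tnc one each
sequences = ["DAGTIAGLNVLR", "TTPSYVAFTDTER", "GGPLSGPYRLR", "EGDPATINAATEIDAPR"]
marker_mzs = [neutral_to_mz(monoisotopic_mass(s)) for s in sequences]

match = match_ims_to_lcms(marker_mzs, id_table, tolerance=0.9)
print(f"matched {match.n_matched} of {match.n_markers} imaging ions")
print(match.proteins.to_string(index=False))

stats = pd.DataFrame({"mz": marker_mzs, "ratio_tam": 2.0, "ratio_tm": 1.0,
                      "auc_tam": 0.9, "auc_tm": 0.5})
report = build_report(match, stats)
print(report[["ims_mz_observed", "sequence", "gene_name",
              "delta_da", "delta_ppm"]].round(4).to_string(index=False))
print("-> Hspa8 is accepted (two matched peptides); the single Ca3 and")
print("   Tenascin-C peptides are matched but not accepted.")
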