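"""Transfer of bottom-up LC-MS/MS peptide identities onto imaging m/z values.

Imaging mass spectrometry of tryptic peptides produces discriminative m/z
values without sequence information (isobaric ions and chimera spectra defeat
on-tissue MS/MS). Identities are therefore borrowed from a bottom-up LC-MS/MS
run on adjacent sections: each imaging ion is converted to a neutral mass
(singly protonated MALDI peptides), compared against the experimental neutral
masses of the identification table, and assigned to the candidate with the
lowest mass difference below a tolerance. A protein is only *accepted* when at
least two of its peptides are independently matched by distinct imaging ions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core_io import PeptideIdTable

log = logging.getLogger(__name__)

# Monoisotopic residue masses (Da), standard atomic-mass reference, 5 decimals.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER_MASS = 18.010565       # H2O, monoisotopic
PROTON_MASS = 1.007276       # H+
OXIDATION_MASS = 15.994915   # variable modification: oxidation (M)


def monoisotopic_mass(sequence: str, oxidized_met_count: int = 0) -> float:
    """Monoisotopic neutral mass of a peptide in Da.

    Sum of residue masses plus one water, plus one oxygen per oxidized
    methionine.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = WATER_MASS
    n_met = 0
    for pos, aa in enumerate(sequence):
        try:
            total += RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(
                f"invalid residue {aa!r} at position {pos} in {sequence!r}"
            ) from None
        if aa == "M":
            n_met += 1
    if oxidized_met_count < 0 or oxidized_met_count > n_met:
        raise ValueError(
            f"oxidized_met_count={oxidized_met_count} exceeds {n_met} methionines"
        )
    return total + oxidized_met_count * OXIDATION_MASS


def mz_to_neutral(mz: float, charge: int = 1) -> float:
    """Neutral mass from an [M+zH]^z+ ion m/z. MALDI peptides: charge 1."""
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    if mz <= PROTON_MASS:
        raise ValueError(f"m/z {mz} at charge {charge} yields nonpositive mass")
    return mz * charge - charge * PROTON_MASS


def neutral_to_mz(neutral_mass: float, charge: int = 1) -> float:
    """Inverse of :func:`mz_to_neutral`."""
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return (neutral_mass + charge * PROTON_MASS) / charge


def ppm_error(delta_da: float, reference_mass: float) -> float:
    """Relative mass error in parts per million."""
    if reference_mass <= 0:
        raise ValueError("reference mass must be positive")
    return delta_da / reference_mass * 1e6


@dataclass
class MatchReport:
    """Assignments of imaging m/z values to LC-MS/MS peptides.

    ``matches`` has one row per assigned imaging ion (ims_mz_observed,
    ims_neutral_mass, sequence, protein_accession, gene_name, description,
    lcms_mass, delta_da, delta_ppm, score); ``proteins`` summarises per-protein
    acceptance under the two-peptide rule. ``n_markers`` / ``n_matched`` give
    the assigned-out-of-total bookkeeping for the run.
    """

    matches: pd.DataFrame
    proteins: pd.DataFrame
    n_markers: int = 0
    n_matched: int = 0
    tolerance: float = 0.9

    def accepted_proteins(self) -> list[str]:
        if self.proteins.empty:
            return []
        return list(self.proteins.loc[self.proteins["accepted"], "protein_accession"])


_MATCH_COLUMNS = [
    "ims_mz_observed", "ims_neutral_mass", "sequence", "protein_accession",
    "gene_name", "description", "lcms_mass", "delta_da", "delta_ppm", "score",
]


def match_ims_to_lcms(
    marker_mzs: list[float] | pd.Series,
    id_table: PeptideIdTable,
    tolerance: float = 0.9,
    charge: int = 1,
) -> MatchReport:
    """Assign each imaging marker m/z to its nearest LC-MS/MS peptide mass.

    A candidate peptide qualifies when |neutral mass difference| < ``tolerance``
    (strictly below, in Da). The winner is the candidate with the lowest
    absolute delta; ties break by lower ppm error, then lexicographic sequence,
    and the tie is logged. A protein is accepted when >= 2 distinct peptide
    sequences are matched by distinct imaging ions.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive (Da)")
    marker_mzs = [float(m) for m in marker_mzs]
    if id_table.rows.empty:
        log.warning("empty identification table: no matches possible")
        return MatchReport(
            matches=pd.DataFrame(columns=_MATCH_COLUMNS),
            proteins=pd.DataFrame(
                columns=["protein_accession", "gene_name", "n_matched_peptides",
                         "accepted"]),
            n_markers=len(marker_mzs), n_matched=0, tolerance=tolerance,
        )

    # Deterministic candidate order regardless of id-table row order.
    table = id_table.rows.sort_values(
        ["sequence", "protein_accession"], kind="mergesort"
    ).reset_index(drop=True)

    rows = []
    for mz in marker_mzs:
        neutral = mz_to_neutral(mz, charge=charge)
        deltas = (table["experimental_neutral_mass"] - neutral).abs()
        in_tol = deltas < tolerance
        if not in_tol.any():
            continue
        cand = table.loc[in_tol].copy()
        cand["delta_da"] = deltas[in_tol]
        cand["delta_ppm"] = cand["delta_da"] / neutral * 1e6
        cand = cand.sort_values(
            ["delta_da", "delta_ppm", "sequence"], kind="mergesort"
        )
        if len(cand) > 1 and cand["delta_da"].iloc[0] == cand["delta_da"].iloc[1]:
            log.info(
                "m/z %.4f: delta tie between %s and %s, keeping %s",
                mz, cand["sequence"].iloc[0], cand["sequence"].iloc[1],
                cand["sequence"].iloc[0],
            )
        best = cand.iloc[0]
        rows.append({
            "ims_mz_observed": mz,
            "ims_neutral_mass": neutral,
            "sequence": best["sequence"],
            "protein_accession": best["protein_accession"],
            "gene_name": best["gene_name"],
            "description": best["description"],
            "lcms_mass": best["experimental_neutral_mass"],
            "delta_da": best["delta_da"],
            "delta_ppm": best["delta_ppm"],
            "score": best["score"],
        })

    matches = pd.DataFrame(rows, columns=_MATCH_COLUMNS)
    if matches.empty:
        proteins = pd.DataFrame(
            columns=["protein_accession", "gene_name", "n_matched_peptides",
                     "accepted"])
    else:
        grouped = (
            matches.groupby("protein_accession", sort=True)
            .agg(gene_name=("gene_name", "first"),
                 n_matched_peptides=("sequence", "nunique"))
            .reset_index()
        )
        grouped["accepted"] = grouped["n_matched_peptides"] >= 2
        proteins = grouped
    return MatchReport(
        matches=matches, proteins=proteins,
        n_markers=len(marker_mzs), n_matched=len(matches), tolerance=tolerance,
    )


REPORT_COLUMNS = [
    "ims_mz_observed", "ims_neutral_mass",
    "ratio_tam", "ratio_tm", "auc_tam", "auc_tm",
    "lcms_mass", "delta_da", "delta_ppm", "score",
    "sequence", "gene_name", "description",
]


def build_report(match_report: MatchReport, marker_table) -> pd.DataFrame:
    """Identification report: one row per matched peptide of an accepted protein.

    Column order follows the field's customary identification-table layout:
    imaging m/z and neutral mass, the tam and tm region-contrast ratios and
    AUCs for that ion, then the LC-MS/MS mass bookkeeping, score, sequence,
    gene and protein description. Peptides are grouped per protein block.
    ``marker_table`` is a :class:`~msiregio.markers.MarkerTable`-style frame
    indexed by column m/z, providing the contrast statistics.
    """
    stats = marker_table.table if hasattr(marker_table, "table") else marker_table
    accepted = set(match_report.accepted_proteins())
    rows = []
    matched = match_report.matches
    for acc in sorted(accepted):
        block = matched[matched["protein_accession"] == acc]
        for _, m in block.sort_values("ims_mz_observed").iterrows():
            hit = stats[abs(stats["mz"] - m["ims_mz_observed"]) < 1e-6]
            if hit.empty:
                raise KeyError(
                    f"marker m/z {m['ims_mz_observed']} absent from marker table"
                )
            srow = hit.iloc[0]
            rows.append({
                "ims_mz_observed": m["ims_mz_observed"],
                "ims_neutral_mass": m["ims_neutral_mass"],
                "ratio_tam": srow.get("ratio_tam", float("nan")),
                "ratio_tm": srow.get("ratio_tm", float("nan")),
                "auc_tam": srow.get("auc_tam", float("nan")),
                "auc_tm": srow.get("auc_tm", float("nan")),
                "lcms_mass": m["lcms_mass"],
                "delta_da": m["delta_da"],
                "delta_ppm": m["delta_ppm"],
                "score": m["score"],
                "sequence": m["sequence"],
                "gene_name": m["gene_name"],
                "description": m["description"],
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
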