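"""Reference constants and the published hcLine cohort summary table.

The ONSEN (ATCOPIA78) family is a heat-stress responsive Ty1/Copia LTR
retrotransposon of *Arabidopsis thaliana* with eight full-length genomic
copies in the Col-0 reference.  The constants below are the published
inputs the analyses start from: the 20-mer LTR head/tail motifs used for
junction-read detection, the gene identifiers of the eight donor copies,
and the per-line private-variant / organelle-coverage summary for the
nine high-copy lines (hcLines) and two control lines (heat-stress-only
and drug-only) of the mobilization experiment.
"""

from __future__ import annotations

import pandas as pd

#: First 20 bases of the ONSEN LTR ("head") and last 20 bases ("tail").
ONSEN_LTR_HEAD = "TGTTGAAAGTTAAACTTGAT"
ONSEN_LTR_TAIL = "AAAAGAATTTTACTCTAACA"

#: Gene identifiers of the eight full-length ONSEN copies in Col-0.
ONSEN_COPY_IDS = (
    "AT1G11265",
    "AT1G21945",
    "AT1G48710",
    "AT1G58140",
    "AT3G32415",
    "AT3G59720",
    "AT3G61330",
    "AT5G13205",
)

#: Approximate length of the ONSEN consensus element (bp).  99 shared
#: sibling insertions of this size add ~490 kb to the genome.
ONSEN_CONSENSUS_LENGTH = 4949

#: Arabidopsis (Col-0) nuclear genome size in bp used for genome-size
#: gain accounting.
ARABIDOPSIS_GENOME_SIZE = 119_000_000

# Published per-line summary: private SNPs / indels / CNVs and organelle
# read-coverage folds relative to the heat-stress-only control.
_HCLINE_ROWS = [
    # line, snps, indels, cnvs, mt_fold, pt_fold
    ("hcLine2", 171, 121, 120, 1.78, 1.46),
    ("hcLine4", 169, 144, 201, 2.01, 1.46),
    ("hcLine7", 158, 115, 88, 1.49, 1.15),
    ("hcLine9", 160, 100, 117, 1.92, 1.46),
    ("hcLine18", 272, 246, 179, 1.56, 1.39),
    ("hcLine31", 195, 152, 138, 1.76, 1.63),
    ("hcLine33", 210, 122, 126, 2.49, 1.49),
    ("hcLine34", 213, 119, 148, 1.61, 1.67),
    ("hcLine45", 197, 156, 106, 2.28, 1.16),
]

_CONTROL_ROWS = [
    ("HS_control", 165, 143, 64, 1.0, 1.0),
    ("AZ_control", 185, 135, 136, 1.9, 1.6),
]

_COLUMNS = ["line", "private_snps", "private_indels", "private_cnvs", "mt_fold", "pt_fold"]


def hcline_table(include_controls: bool = True) -> pd.DataFrame:
    """Published cohort summary as a DataFrame indexed by line name."""
    rows = _HCLINE_ROWS + (_CONTROL_ROWS if include_controls else [])
    return pd.DataFrame(rows, columns=_COLUMNS).set_index("line")
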