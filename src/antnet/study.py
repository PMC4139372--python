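"""The packaged Cerrado ant-plant field dataset and its printed structure.

The package ships the study's full incidence table: 31 ant species
(rows) by 9 extrafloral-nectary tree species (columns), each cell the
number of tagged individuals of that plant species (30 per species, 270
in total) on which the ant was recorded over the two census years
combined.  Row totals are validated against an independent checksum at
load time so a transcription error cannot pass silently.

Per-year species membership is also published: two ant species were seen
only in the first census year and five only in the second.  Restricting
the combined table to each year's species list yields label-level
per-year networks (26 and 29 ant species) sufficient for turnover and
richness accounting; the per-year cell counts themselves were never
published, so quantitative per-year metrics are not reconstructable.
"""

from __future__ import annotations

from importlib import resources

from .matrix import InteractionMatrix, read_matrix

__all__ = [
    "N_INDIVIDUALS_PER_PLANT",
    "ONLY_YEAR_1",
    "ONLY_YEAR_2",
    "ROW_TOTAL_CHECKSUMS",
    "fixture_table1",
    "year_networks",
]

N_INDIVIDUALS_PER_PLANT = 30

#: Ant species recorded only in the first census year (2009).
ONLY_YEAR_1 = ("Crematogaster bruchi", "Linepithema aztecoides")

#: Ant species recorded only in the second census year (2010).
ONLY_YEAR_2 = (
    "Camponotus lespesii",
    "Camponotus vittatus",
    "Cephalotes atratus",
    "Forelius brasiliensis",
    "Ectatomma planidens",
)

#: Published per-ant row totals, kept separate from the cell data as a
#: transcription checksum.
ROW_TOTAL_CHECKSUMS = {
    "Brachymyrmex sp.1": 53,
    "Camponotus sp.1": 4,
    "Camponotus crassus": 152,
    "Camponotus blandus": 55,
    "Camponotus trapeziceps": 19,
    "Camponotus leydigi": 6,
    "Camponotus lespesii": 2,
    "Camponotus vittatus": 3,
    "Crematogaster erecta": 16,
    "Crematogaster bruchi": 10,
    "Pheidole sp.1": 6,
    "Pheidole sp.2": 5,
    "Solenopsis sp.1": 12,
    "Solenopsis sp.2": 8,
    "Cephalotes sp.1": 1,
    "Cephalotes pusillus": 122,
    "Cephalotes bruchi": 2,
    "Cephalotes atratus": 1,
    "Nesomyrmex spininodis": 9,
    "Azteca sp.1": 27,
    "Linepithema aztecoides": 1,
    "Forelius brasiliensis": 1,
    "Pseudomyrmex sp.1": 3,
    "Pseudomyrmex sp.2": 1,
    "Pseudomyrmex gracilis": 63,
    "Pseudomyrmex flavidulus": 61,
    "Gnamptogenys semiferox": 3,
    "Ectatomma tuberculatum": 36,
    "Ectatomma edentatum": 2,
    "Ectatomma planidens": 2,
    "Pachycondyla villosa": 7,
}


def fixture_table1() -> InteractionMatrix:
    """Load the packaged 31 x 9 incidence table, verifying row totals."""
    with resources.as_file(
        resources.files("antnet.data").joinpath("table1.csv")
    ) as path:
        M = read_matrix(
            path,
            dialect="matrix",
            n_individuals_per_plant=N_INDIVIDUALS_PER_PLANT,
            period_label="combined",
        )
    if set(M.ant_labels) != set(ROW_TOTAL_CHECKSUMS):
        raise RuntimeError("packaged fixture: ant label set mismatch")
    for ant, expected in ROW_TOTAL_CHECKSUMS.items():
        total = int(M.row(ant).sum())
        if total != expected:
            raise RuntimeError(
                f"packaged fixture: row total for {ant!r} is {total}, "
                f"expected {expected}"
            )
    return M


def year_networks() -> tuple[InteractionMatrix, InteractionMatrix]:
    """Label-level per-year networks from the combined table.

    Each year's network keeps the combined cell counts restricted to the
    ant species recorded that year.  Species membership (hence richness
    and turnover) is exact; cell counts remain two-year pools because the
    per-year counts were never published.
    """
    M = fixture_table1()
    from dataclasses import replace

    year1 = replace(
        M.subset_ants([a for a in M.ant_labels if a not in ONLY_YEAR_2]),
        period_label="2009",
    )
    year2 = replace(
        M.subset_ants([a for a in M.ant_labels if a not in ONLY_YEAR_1]),
        period_label="2010",
    )
    return year1, year2
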