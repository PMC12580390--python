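"""Gate a tiny per-cell multiplex-IF export into phenotypes.

Cells are called CAF when α-SMA⁺/CK⁻, TAEC when CD31⁺/CK⁻, tumor when
CK⁺; anything else is "other". Rules are applied in priority order, so an
α-SMA⁺/CD31⁺/CK⁻ double positive resolves deterministically to CAF.
"""

import io

from spatialtme import assign_phenotypes, parse_cell_table

CSV = """\
patient_id,core_id,cell_id,x_um,y_um,ck_pos,asma_pos,cd31_pos,pdl1_pos,pd1_pos
P1,C1,c1,10.0,20.0,0,1,0,0,0
P1,C1,c2,35.0,22.0,0,0,1,0,0
P1,C1,c3,50.0,60.0,1,0,0,1,0
P1,C1,c4,70.0,61.0,0,1,1,0,0
P1,C1,c5,90.0,15.0,0,0,0,0,1
"""

table = parse_cell_table(io.StringIO(CSV))[0]
gated, n_conflicts = assign_phenotypes(table, count_conflicts=True)

for cell in gated.cells:
    print(f"{cell.cell_id}: {cell.phenotype}")
print(f"counts: {gated.phenotype_counts()}")
print(f"double-positive cells resolved by priority: {n_conflicts}")
# c1 is a fibroblast, c2 an endothelial cell, c3 a PD-L1+ tumor cell,
# c4 matches both stromal rules (counted as a conflict, labeled CAF),
# c5 is a PD-1+ non-epithelial cell labeled "other".
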