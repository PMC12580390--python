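import io

import numpy as np
import pytest

from spatialtme import CellRecord, CellTable, parse_cell_table

CSV_HEADER = "patient_id,core_id,cell_id,x_um,y_um,ck_pos,asma_pos,cd31_pos,pdl1_pos,pd1_pos"


def make_csv(rows):
    return io.StringIO("\n".join([CSV_HEADER, *rows]) + "\n")


def make_table(points, patient_id="P1", core_id="C1", width=1000.0,
               height=1000.0):
    """CellTable from [(x, y, phenotype), ...] with consistent marker flags."""
    marker_for = {"CAF": "aSMA", "TAEC": "CD31", "tumor": "CK"}
    cells = []
    for i, (x, y, pheno) in enumerate(points):
        markers = {"CK": 0, "aSMA": 0, "CD31": 0, "PDL1": 0, "PD1": 0}
        if pheno in marker_for:
            markers[marker_for[pheno]] = 1
        cells.append(CellRecord(f"c{i}", float(x), float(y), markers,
                                phenotype=pheno))
    return CellTable(patient_id, core_id, width, height, cells)


@pytest.fixture
def three_row_csv():
    return make_csv([
        "P1,C1,c1,10.0,20.0,0,1,0,0,0",
        "P1,C1,c2,30.0,40.0,0,0,1,0,0",
        "P1,C1,c3,50.0,60.0,1,0,0,1,0",
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def brute_force_nnd(source, target):
    """All-pairs O(n*m) nearest-neighbor oracle."""
    src = np.asarray(source, float)
    tgt = np.asarray(target, float)
    d = np.sqrt(((src[:, None, :] - tgt[None, :, :]) ** 2).sum(-1))
    return d.min(axis=1)
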