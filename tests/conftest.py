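import pandas as pd
import pytest

from idiorep.airr_io import RearrangementSet, translate_nt
from idiorep.synthetic_data import germline_reference

_DEFAULTS = {
    "locus": "IGH",
    "v_call": "IGHV4-34*01",
    "j_call": "IGHJ4*01",
    "c_call": "IGHM",
    "productive": True,
    "duplicate_count": 1,
    "subject_id": "S1",
    "subset_label": "CD27+IgM+",
}


def make_set(rows: list[dict]) -> RearrangementSet:
    """Build a RearrangementSet from sparse row dicts; sensible AIRR defaults."""
    full = []
    for i, row in enumerate(rows):
        rec = dict(_DEFAULTS)
        rec["sequence_id"] = f"seq{i + 1:03d}"
        junction = row.get("junction", "TGTGCTAGATGG")  # C-A-R-W
        rec["junction"] = junction
        rec["junction_aa"] = row.get(
            "junction_aa",
            translate_nt(junction) if len(junction) % 3 == 0 else "",
        )
        rec["sequence"] = row.get("sequence", "CAGGTT" + junction + "ACTGTT")
        rec.update(row)
        full.append(rec)
    columns = ["sequence_id", "sequence", "junction", "junction_aa", *_DEFAULTS]
    return RearrangementSet(pd.DataFrame(full, columns=columns if not full else None))


@pytest.fixture(scope="session")
def v434():
    """Synthetic IGHV4-34-like germline reference."""
    return germline_reference("IGHV4-34")


@pytest.fixture()
def v434_record(v434):
    """A germline (unmutated) IGHV4-34 rearrangement record."""
    junction = "TGTGCTAGAGATTATTGG"  # CARDYW
    return {
        "sequence_id": "rec1",
        "v_call": "IGHV4-34*01",
        "sequence": v434.sequence_nt + junction + "ACTACTGTT",
        "junction": junction,
    }
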