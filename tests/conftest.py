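from __future__ import annotations

import random

import pytest

from seromap.peptides import PeptideRecord, SampleDesign, SampleInfo
from seromap.repertoire import AntibodyClone, derive_cdr3_bounds

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_clone(
    record_id: str,
    sequence_aa: str,
    cdr3_aa: str,
    isotype: str = "IgG1",
    v_call: str = "IGHV1-2",
    d_call: str | None = "IGHD3-3",
    j_call: str = "IGHJ4",
    read_count: int = 1,
    region_bounds: dict | None = None,
) -> AntibodyClone:
    if region_bounds is None:
        region_bounds = {"CDR3": derive_cdr3_bounds(sequence_aa, cdr3_aa)}
    clone = AntibodyClone(
        record_id=record_id,
        sequence_aa=sequence_aa,
        cdr3_aa=cdr3_aa,
        isotype=isotype,
        v_call=v_call,
        d_call=d_call,
        j_call=j_call,
        read_count=read_count,
        region_bounds=region_bounds,
    )
    clone.validate()
    return clone


def random_clone(rng: random.Random, record_id: str, length: int = 30) -> AntibodyClone:
    seq = "".join(rng.choice(AA20) for _ in range(length))
    cdr3_len = rng.randint(4, 8)
    start = rng.randint(0, length - cdr3_len)
    return make_clone(
        record_id,
        seq,
        seq[start:cdr3_len + start],
        isotype=rng.choice(["IgG1", "IgM", "IgA1"]),
        v_call=rng.choice(["IGHV1-2", "IGHV3-23"]),
        j_call=rng.choice(["IGHJ4", "IGHJ6"]),
        read_count=rng.randint(1, 50),
        region_bounds={"CDR3": (start, start + cdr3_len)},
    )


@pytest.fixture
def design_2x2() -> SampleDesign:
    return SampleDesign(
        samples=(
            SampleInfo("E1", "elution", 1),
            SampleInfo("E2", "elution", 2),
            SampleInfo("FT1", "flow_through", 1),
            SampleInfo("FT2", "flow_through", 2),
        )
    )


def make_peptide(sequence: str, elution: list[float], flow: list[float]) -> PeptideRecord:
    intensities = {f"E{i + 1}": v for i, v in enumerate(elution)}
    intensities.update({f"FT{i + 1}": v for i, v in enumerate(flow)})
    return PeptideRecord(sequence=sequence, intensities=intensities)
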