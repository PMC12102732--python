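import numpy as np
import pytest

from cimmerge import PeptideID, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def protein():
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list(AA), size=60))
    return ProteinRecord("PROT1", seq)


def make_pid(
    sequence="PEPTIDES",
    start=1,
    protein_id="PROT1",
    modification="",
    plgs_score=8.0,
    rt=10.0,
    dt_bin=50.0,
    intensity=1e5,
    products_per_aa=1.0,
    matched_products=8,
    consecutive_products=4,
    sum_product_intensity=5e4,
    mh_ppm_error=1.0,
    replicate_id="rep1",
    trendline_tag="11_13",
    **overrides,
):
    """A valid PeptideID with sensible defaults; end derives from sequence."""
    fields = dict(
        protein_id=protein_id,
        sequence=sequence,
        start=start,
        end=start + len(sequence) - 1,
        modification=modification,
        plgs_score=plgs_score,
        rt=rt,
        dt_bin=dt_bin,
        intensity=intensity,
        products_per_aa=products_per_aa,
        matched_products=matched_products,
        consecutive_products=consecutive_products,
        sum_product_intensity=sum_product_intensity,
        mh_ppm_error=mh_ppm_error,
        replicate_id=replicate_id,
        trendline_tag=trendline_tag,
    )
    fields.update(overrides)
    return PeptideID(**fields)


@pytest.fixture
def pid_factory():
    return make_pid
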