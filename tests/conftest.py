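import numpy as np
import pandas as pd
import pytest

from glycoforms.glycans import parse_composition
from glycoforms.ingest import GlycopeptideRecord
from glycoforms.matrix import IntensityMatrix, SampleDesign


def make_record(
    peptide="PEPTIDEK",
    protein="P1",
    site=100,
    composition="HexNAc(2)Hex(5)",
    ms1=1e6,
    reporters=(),
    n_psms=1,
):
    return GlycopeptideRecord(
        peptide=peptide,
        protein=protein,
        site_position=site,
        composition=parse_composition(composition),
        ms1_intensity=ms1,
        reporter_intensities=tuple(reporters),
        n_psms=n_psms,
    )


def features_to_records(features: pd.DataFrame) -> list[GlycopeptideRecord]:
    """Build unique-glycopeptide records from a simulator feature table."""
    return [
        make_record(
            peptide=row.get("peptide", row["feature_id"].split("|")[0]),
            protein=row["protein"],
            site=int(str(row.get("site_position", row.get("site", "x|100"))).split("|")[-1]),
            composition=row["composition"],
            ms1=row.get("true_fraction", 1.0) * 1e7,
        )
        for _, row in features.iterrows()
    ]


def two_group_matrix(seed, n_features=200, n_spiked=0, log2fc=2.0, noise_sd=0.1, n_rep=3):
    """Minimal log2-scale two-group matrix with optional spiked features."""
    rng = np.random.default_rng(seed)
    channels = [f"ctl_r{i}" for i in range(1, n_rep + 1)] + [
        f"trt_r{i}" for i in range(1, n_rep + 1)
    ]
    design = SampleDesign(
        pd.DataFrame(
            {
                "condition": ["control"] * n_rep + ["treatment"] * n_rep,
                "replicate": [f"r{i}" for i in range(1, n_rep + 1)] * 2,
            },
            index=pd.Index(channels, name="channel"),
        )
    )
    base = rng.normal(10, 1.5, (n_features, 1))
    noise = rng.normal(0, noise_sd, (n_features, 2 * n_rep))
    values = base + noise
    values[:n_spiked, n_rep:] += log2fc
    frame = pd.DataFrame(values, columns=channels, index=[f"f{i}" for i in range(n_features)])
    return IntensityMatrix(frame, design, scale="log2")


@pytest.fixture
def simple_records():
    return [
        make_record(peptide="AAAK", protein="P1", site=50, composition="HexNAc(2)Hex(5)", ms1=3e6),
        make_record(peptide="CCCK", protein="P1", site=50, composition="HexNAc(2)Hex(9)", ms1=1e6),
        make_record(peptide="DDDK", protein="P1", site=120, composition="HexNAc(2)Hex(5)", ms1=2e6),
        make_record(peptide="EEEK", protein="P2", site=30, composition="HexNAc(4)Hex(5)Fuc(1)", ms1=5e6),
    ]
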