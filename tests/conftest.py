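import dataclasses

import pytest

from splicestage import GeneModel, SimConfig, simulate_sample


@pytest.fixture
def gene_g() -> GeneModel:
    """Three-exon plus-strand gene: exons [101,200], [301,400], [501,600]
    (1-based inclusive) on chrT."""
    return GeneModel("G", "chrT", "+", ((100, 200), (300, 400), (500, 600)))


@pytest.fixture
def gene_g_minus() -> GeneModel:
    """Same exon coordinates on the minus strand (exon 1 = [501,600])."""
    return GeneModel("G", "chrT", "-", ((500, 600), (300, 400), (100, 200)))


@pytest.fixture
def sam_writer(tmp_path):
    """Write a minimal unpaired SAM from (qname, flag, pos1, cigar) rows."""

    def write(rows, chrom="chrT", length=1000, name="reads.sam"):
        lines = [
            "@HD\tVN:1.6\tSO:coordinate",
            f"@SQ\tSN:{chrom}\tLN:{length}",
        ]
        for q, flag, pos1, cigar in sorted(rows, key=lambda r: r[2]):
            lines.append(
                f"{q}\t{flag}\t{chrom}\t{pos1}\t60\t{cigar}\t*\t0\t0\t*\t*"
            )
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return write


@pytest.fixture(scope="session")
def mature_sample(tmp_path_factory):
    cfg = SimConfig(mix_unspliced=0, mix_partial=0, mix_mature=1,
                    n_pairs=1500, seed=21)
    return simulate_sample(cfg, tmp_path_factory.mktemp("mature"), "mature")


@pytest.fixture(scope="session")
def unspliced_sample(tmp_path_factory):
    cfg = SimConfig(mix_unspliced=1, mix_partial=0, mix_mature=0,
                    n_pairs=1500, seed=22)
    return simulate_sample(cfg, tmp_path_factory.mktemp("unspliced"),
                           "unspliced")


@pytest.fixture(scope="session")
def mixture_sample(tmp_path_factory):
    """60/40 unspliced/mature mixture."""
    cfg = SimConfig(mix_unspliced=0.6, mix_partial=0, mix_mature=0.4,
                    n_pairs=3000, seed=23)
    return simulate_sample(cfg, tmp_path_factory.mktemp("mixture"), "mixture")


@pytest.fixture(scope="session")
def sim_config_factory():
    def make(**kwargs) -> SimConfig:
        return dataclasses.replace(SimConfig(), **kwargs)

    return make
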