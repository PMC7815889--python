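import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mbqtl.containers import GenotypeMatrix
from mbqtl.simulate import SimulationConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def make_genotypes(dosage, mafs=None, annotation="intron", gene="GENE",
                   ibd_locus=False, variant_ids=None, sample_ids=None):
    """Hand-build a GenotypeMatrix from a dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(n)]
    if variant_ids is None:
        variant_ids = [f"v{j:03d}" for j in range(m)]
    ann = [annotation] * m if isinstance(annotation, str) else list(annotation)
    genes = [gene] * m if isinstance(gene, str) else list(gene)
    loci = [ibd_locus] * m if isinstance(ibd_locus, bool) else list(ibd_locus)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, m + 1),
            "ref": "A",
            "alt": "C",
            "gene": genes,
            "annotation": ann,
            "ibd_locus": loci,
        },
        index=pd.Index(variant_ids, name="variant_id"),
    )
    g = GenotypeMatrix(np.array(sample_ids, dtype=object), variants, dosage)
    g.recompute_stats()
    if mafs is not None:
        g.variants["maf"] = mafs
    return g


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(
        n_controls=120, n_cases=60, n_common_variants=30, n_rare_ptvs=25,
        n_cnv_genes=8, n_taxa=12, n_pathways=10,
        zero_inflation_range=(0.0, 0.3), n_reference=50, seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_dataset(tiny_config)
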