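import numpy as np
import pytest
from shapely.geometry import box

from landgen.landcover import CountyEraMap
from landgen.popgen import GenotypeMatrix
from landgen.resistance import SiteSample

# planar offset keeps toy coordinates outside the lon/lat-degree range
OX, OY = 10_000.0, 10_000.0


def strip_map(widths, proportions, era=2012, height=1_000.0):
    """Horizontal strip of abutting rectangular counties C1, C2, ..."""
    counties, props = {}, {}
    x = OX
    for i, (w, p) in enumerate(zip(widths, proportions), start=1):
        counties[f"C{i}"] = box(x, OY, x + w, OY + height)
        props[f"C{i}"] = p
        x += w
    return CountyEraMap(counties=counties, proportions={era: props})


@pytest.fixture
def site_pair():
    a = SiteSample("A", OX, OY + 500.0, "PA")
    b = SiteSample("B", OX + 1_000.0, OY + 500.0, "PB")
    return a, b


def genotypes(calls, pops=None, ids=None):
    """GenotypeMatrix from a plain 2-D list/array of codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    pops = pops if pops is not None else ["P1"] * n
    ids = ids if ids is not None else [f"I{i}" for i in range(n)]
    return GenotypeMatrix(
        individual_ids=list(ids),
        population_labels=list(pops),
        locus_ids=[f"L{j}" for j in range(L)],
        calls=calls,
    )


def hwe_genotypes(rng, freqs, n_per_pop, pops):
    """Binomial (Hardy-Weinberg) genotypes: freqs is (n_pops, n_loci)."""
    blocks, labels = [], []
    for k, pop in enumerate(pops):
        blocks.append(rng.binomial(2, freqs[k], size=(n_per_pop, freqs.shape[1])))
        labels += [pop] * n_per_pop
    return genotypes(np.vstack(blocks), pops=labels)
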