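import numpy as np
import pytest

from bacuchar import CircularGenome
from bacuchar.synthetic import (
    GenomeManifest,
    PlantedMotif,
    PlantedOrf,
    chinnpv_like_manifest,
    gen_genome,
    random_background,
)


@pytest.fixture(scope="session")
def chinnpv_like():
    """Synthetic genome emulating the characterized isolate's repeat
    landscape (three tandem arrays, no hr) plus its truth tables."""
    return gen_genome(chinnpv_like_manifest(seed=7))


@pytest.fixture(scope="session")
def planted_orf_genome():
    """Genome with three reference-derived ORFs and two planted promoter
    motifs; the reference proteins double as labelled proteomes."""
    rng = np.random.default_rng(11)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    prots = {f"ref{i}": "M" + "".join(rng.choice(list(aas), 79))
             for i in range(3)}
    orfs = tuple(
        PlantedOrf(start=1000 + i * 1500, strand="+" if i % 2 == 0 else "-",
                   n_codons=80, source_protein=prots[f"ref{i}"],
                   target_identity=0.8)
        for i in range(3)
    )
    manifest = GenomeManifest(
        seed=5, length=8000, orfs=orfs,
        motifs=(PlantedMotif(motif="TATAAAA", orf_index=0, offset=-100),
                PlantedMotif(motif="CAGT", orf_index=1, offset=-60)),
    )
    genome, truth = gen_genome(manifest)
    proteomes = {"core": {"ref0": prots["ref0"]},
                 "alpha_conserved": {"ref1": prots["ref1"]},
                 "shared": {"ref2": prots["ref2"]}}
    return genome, truth, manifest, proteomes


def random_genome(seed: int, length: int, gc: float = 0.4,
                  topology: str = "circular") -> CircularGenome:
    rng = np.random.default_rng(seed)
    seq = random_background(rng, length, gc).tobytes().decode()
    return CircularGenome(f"rand{seed}", seq, topology=topology)
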