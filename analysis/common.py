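"""Shared study conditions for the analysis drivers.

One master seed drives every generator; per-stage seeds derive from it by
fixed offsets so each numbered script can regenerate exactly the same
inputs without depending on another script having run first.
"""

from pathlib import Path

from cacmir import synthetic_data as sd

RESULTS = Path(__file__).resolve().parent.parent / "results"
MASTER_SEED = 20170603  # publication date of the study this pipeline mirrors

N_REFS = 20
N_ESTS = 200
EST_LENGTH = 330
N_PLANTED = 20
N_HAIRPIN_PLANTS = 10
MISMATCHES = 2
N_TRANSCRIPTS = 20
TRANSCRIPT_LENGTH = 300
N_NODES = 150
BA_ATTACH = 3
N_COMPLEXES = 8


def reference_mirnas():
    return sd.gen_reference_mirnas(N_REFS, seed=MASTER_SEED)


def est_set():
    return sd.gen_ests_with_homologs(
        reference_mirnas(),
        N_ESTS,
        EST_LENGTH,
        N_PLANTED,
        MISMATCHES,
        seed=MASTER_SEED + 1,
        n_hairpin_plants=N_HAIRPIN_PLANTS,
    )


def site_specs(refs):
    recipes = [
        (0.0, 0, 0), (0.5, 0, 1), (1.0, 1, 0), (1.5, 1, 1),
        (2.0, 2, 0), (2.5, 1, 1), (3.0, 3, 0), (1.0, 0, 1),
    ]
    return [
        sd.SiteSpec(refs[i % len(refs)].id, expectation=e, n_mismatches=nm, n_gu=ng)
        for i, (e, nm, ng) in enumerate(recipes)
    ]


def transcriptome(refs):
    return sd.gen_transcriptome_with_sites(
        refs, N_TRANSCRIPTS, TRANSCRIPT_LENGTH, site_specs(refs), seed=MASTER_SEED + 2
    )


def interactions():
    return sd.gen_interactions(
        N_NODES,
        model="BA",
        n_edges_or_attach=BA_ATTACH,
        n_complexes=N_COMPLEXES,
        complex_size_range=(3, 6),
        seed=MASTER_SEED + 3,
    )
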