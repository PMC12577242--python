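"""Mine essential CDR3 motifs by occlusion saliency.

Each 3-mer (and gapped-mer X*XX / XX*X) window of the high-scoring
validation-case sequences is zero-masked; the drop in classifier
probability is the window's contribution.  Motifs in the top 1.5% of mean
contributions that recur often enough are flagged essential.
"""

from tcrars.pipeline import run_motif_mining
from tcrars.repertoire_io import prepare_cohort
from tcrars.synthetic import SimulationConfig, generate_cohort

cohort, truth = generate_cohort(
    SimulationConfig(n_cases=16, n_controls=16, clonotypes_per_subject=250, seed=11)
)
cohort = prepare_cohort(cohort)
run = run_motif_mining(
    cohort, seed=3, min_counts={"XXX": 20, "X*XX": 5, "XX*X": 5}
)
print(f"analyzed {len(run.analyzed_sequences)} high-scoring case sequences\n")
for pattern, res in run.results.items():
    print(f"pattern {pattern}: {len(res['selected'])} essential motifs")
    for rec in res["selected"][:6]:
        front, mid, tail = res["profile"].segment_fractions[rec.motif]
        planted = " (planted)" if rec.motif in truth.signal_motifs else ""
        print(
            f"  {rec.motif:<6s} mean delta={rec.mean_delta:.3f} "
            f"n={rec.occurrence_count:<4d} tail={tail:.2f}{planted}"
        )
print(
    "\nmean delta = average probability drop when the motif is occluded; "
    "tail = fraction of occurrences starting in the C-terminal third, where "
    "the generator plants its signal (mirroring J-segment-encoded tails)."
)
recovered = {r.motif for res in run.results.values() for r in res["selected"]}
print(f"planted motifs recovered: {sorted(set(truth.signal_motifs) & recovered)}")
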