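"""Excise the provirus, reconstitute the attV junction, and check PCR geometry.

The excised circular genome keeps exactly one att copy (attV) at position 0.
Primers that straddle the junction only amplify on the circular form — the
computational counterpart of the gel assay distinguishing the integrated
provirus from its excised, circularized state.
"""

from pleoprophage import (
    FixtureSpec,
    call_proviruses,
    insilico_pcr,
    make_genome_with_provirus,
    reintegrate,
    revcomp,
)

genome, _ = make_genome_with_provirus(FixtureSpec(seed=1))
call = call_proviruses(genome)[0]
circle = call.circular_genome

print(f"excised circle: {len(circle):,} bp, att copies on circle: {circle.count(call.repeat_seq)}")
print(f"re-integration reproduces the chromosome byte-identically: {reintegrate(call, genome) == genome.seq}")

# primers straddling the attV junction (60 bp either side)
fwd = circle[-60:-40]
rev = revcomp(circle[40:60])
print(f"attV-spanning primers on circular template: {insilico_pcr(circle, 'circular', fwd, rev)} bp")
print(f"same primers, linear template:              {insilico_pcr(circle, 'linear', fwd, rev)} (no product)")
# Only the circular topology yields the 120-bp junction amplicon: the two
# binding sites face away from each other on the linear sequence.
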