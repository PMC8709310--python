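"""Call tandem and segmental gene duplications across five genomes.

Materializes the reference duplication layout (two D-type and three
S-type genomes), classifies homologous gene pairs by the 50-kb same-
chromosome rule, and merges identical calls within each genome group.
"""

from dhnkit import call_duplications, merge_duplication_events
from dhnkit import simulate as sim
from dhnkit.loci import events_table

loci, groups = sim.reference_locus_table(gap_tandem=10_000, seed=0)
calls = call_duplications(loci)
events = merge_duplication_events(calls, groups)

print(events_table(events).to_string(index=False))
kinds = [e.kind for e in events]
print(f"\n{kinds.count('tandem')} tandem + {kinds.count('segmental')} segmental events.")
print("A pair is tandem when homologs sit on one chromosome within 50 kb;")
print("cross-chromosome homologs are segmental. Identical calls from genomes")
print("of one group (e.g. Bd21 and the ABR113 D subgenome) count once.")
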