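# famcensus

A gene-family census toolkit for plant genomes, built around the workflow
used to survey Snf2-family chromatin-remodeler ATPases across predicted
proteomes. Snf2 ATPases are the motor subunits of chromatin-remodeling
complexes; they are defined by a conserved ~400 aa ATPase region made of
the SNF2_N and Helicase_C Pfam domains, and plant genomes carry them in
18 subfamilies (DRD1, Rad5/16, Snf2, ERCC6, ...). `famcensus` implements
every decision step of such a census and ships a synthetic-data module
that generates all inputs with planted ground truth, so the full pipeline
is testable without any genome downloads.

## What it does

1. **Candidate calling** (`famcensus.scan`) — a protein is a family
   candidate iff length > 200 aa, it has ≥1 SNF2_N and ≥1 Helicase_C
   domain match with E < 10⁻³, and its ATPase-region profile bitscore is
   ≥ 200. Isoforms collapse to one representative per locus; seed sets
   for profile construction are curated (≥ 200 aa, no
   "putative"/"uncharacterized"/"predicted" descriptions); the ATPase
   region is extracted with 30 aa flanks for tree building.
2. **Locus recall** (`famcensus.recall`) — protein-vs-genome hits
   (E < 10) are single-linkage clustered with a 15 kb interval-gap
   cutoff; clusters become regions for an external gene predictor and are
   partitioned against an existing annotation into
   annotated-recovered / unannotated-new / annotation-only.
3. **Subfamily classification** (`famcensus.classify`) — unlabeled
   gene-tree leaves take the subfamily of the smallest clade containing a
   reference leaf (conservative "not classified" on disagreement), and
   the species × subfamily census matrix is built with per-subfamily mean,
   population sd, per-cell deviation in sd units, and quartiles of the
   per-species totals.
4. **Reconciliation** (`famcensus.reconcile`) — LCA parsimony mapping of
   a gene tree onto a species tree: duplication/speciation calls per
   node, loss counts per edge, in-paralog groups, and in-paralog calls
   relative to a species pair's divergence.
5. **Protein features** (`famcensus.features`) — FoldIndex disorder
   scoring, score = 2.785·⟨H⟩ − |⟨R⟩| − 1.151 with ⟨H⟩ the window-mean
   Kyte–Doolittle hydropathy rescaled to [0, 1] and ⟨R⟩ the mean net
   charge; regions below −0.2 are called disordered. Accessory-domain
   architecture summaries (BROMO, QLQ, HSA, ...) per protein.
6. **Expression** (`famcensus.expression`) — FPKM classes low (≤ 5),
   moderate (5–200], high (> 200), per-gene expressed flags, and the
   dense gene × library matrix.
7. **Synthetic data** (`famcensus.simulate`) — proteomes with planted
   members and rule-specific decoys, genome hits at controlled locus
   spacings, gene trees with recoverable planted duplication/loss
   histories, and FPKM tables drawn inside planned category intervals.

## Worked example

```python
from famcensus.simulate import SimProteomeSpec, gen_proteome
from famcensus.scan import filter_candidates
from famcensus.reconcile import reconcile

sim = gen_proteome(SimProteomeSpec(n_true=5, n_decoys_single_domain=3,
                                   n_decoys_short=2, seed=1))
called = filter_candidates(sim.proteins, sim.domain_hits, sim.scores)
print(sorted(c.protein.id for c in called))
# ['true001.1', 'true002.1', 'true003.1', 'true004.1', 'true005.1']

res = reconcile("((AtCHR12,AtCHR23),Sly1);", "(Ath,Sly);",
                {"AtCHR12": "Ath", "AtCHR23": "Ath", "Sly1": "Sly"})
print(res.n_duplications, res.n_losses, res.inparalog_groups)
# 1 0 [frozenset({'AtCHR23', 'AtCHR12'})]
```

The scan recovers exactly the five planted family members — both decoy
classes (single-domain and fragment-length) are rejected. The
reconciliation example is the classic in-paralog situation: two
same-species genes sister to each other with a single ortholog in a
second species imply one duplication after the speciation and no losses,
so the pair forms an in-paralog group.

Every stage is also available from the shell:

```
famcensus simulate proteome --out sim/
famcensus scan --proteome sim/proteome.fasta --domtbl sim/domain_hits.tsv \
               --scores sim/profile_scores.tsv --out scan/
famcensus reconcile --gene-tree g.nwk --species-tree s.nwk \
                    --gene-species map.tsv --out rec/
famcensus census --inputs inputs.yaml --config cfg.yaml
```

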