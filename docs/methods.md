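# Methods

This note documents the models, conventions and numerical choices behind
`synspeech`, and what the synthetic-data tests do and do not establish
about real clinical speech.

## Dependency distance

Every non-root token contributes one link; its distance is the absolute
difference of the linear positions of dependent and governor, so adjacent
attachments score 1 and a chain-structured sentence has MDD exactly 1.
Sentence MDD divides the summed distances by a convention-dependent
denominator; text MDD pools numerators and denominators over all
sentences of a transcript (it is a ratio of sums, not a mean of ratios,
so long sentences weigh more).

Published practice is internally inconsistent about punctuation: the
standard worked example sums the punctuation link (distance 6) and
divides by words − 1 = 9 to obtain 2.33, while the stated rule excludes
punctuation and root links. Rather than guessing an intent, both are
shipped as presets:

| preset | punctuation links | denominator |
|---|---|---|
| `published_example` | included | non-punctuation words − 1 per sentence |
| `stated_rule` (default for new analyses) | excluded | words − sentences |

A third denominator mode, `links_count`, divides by the number of links
actually used; it reproduces printed per-example values such as 1.67 for
"The mother was drying her dishes." where the divisor is evidently the
link count. Sentences with no usable link (single-token fragments,
phrase-only units) are undefined: they are excluded from both numerator
and denominator and counted in `MddResult.n_sentences_undefined`, never
propagated as NaN or silently scored 0.

Values are carried at full precision; rounding to 2 d.p. happens only at
reporting boundaries.

## Index catalogue

The twenty indices are operational definitions over (relation, POS)
predicates on a canonical Universal Dependencies v2 label set. Treebanks
parsed with Stanford/CoreNLP-style labels load through a mapping table
(`prep`→case, `pobj`→nmod, `dobj`→obj, `rcmod`→acl:relcl, `vmod`→acl,
`poss`→nmod:poss, …), so both dialects yield the same counts. Choices
that the index names themselves leave open:

- **Nominal** means NOUN/PROPN tokens; pronouns are included unless the
  index is marked "no pronouns" (`_NN`).
- **Clause** means the root token plus every token bearing a clausal
  relation (ccomp, xcomp, advcl, acl, acl:relcl) plus verb-headed
  coordination (conj on a VERB/AUX). Verbless fragments therefore count
  as one clause, which keeps per-clause denominators defined for the
  phrase-only discourse units that transcripts of connected speech
  contain.
- **Object of a preposition** is a nominal governing a `case` ADP child
  (UD attaches the adposition below the noun); "prepositions per X"
  counts the case markers inside nmod/obl modifiers of X.
- **Nominal complement** (`av_ncomp_deps_NN`) is read as a nominal
  serving as copular predicate (a token with a `cop` child); "dependents
  per nominal complement" averages its non-punctuation child count. This
  is an interpretation — the name is ambiguous between copular and
  noun-complement readings — and is stated here as the contract.
- `conj_per_cl` counts all coordinating-conjunction (`cc`) tokens per
  clause; `cc_per_cl` restricts to clause-level coordinators, i.e. `cc`
  tokens attached to a verbal head.
- Standard-deviation indices (`*_stdev`, `cl_ndeps_std_dev`) use the
  population (divide-by-N) form over the observed per-unit dependent
  counts: they describe the observed units, not an estimate for a
  superpopulation.

A zero denominator makes an index undefined (`None`/NaN downstream) with
its support count recorded; downstream models drop missing rows listwise.

TTR is distinct lowercased non-punctuation forms over total
non-punctuation tokens. Disfluent repetitions count as tokens on
purpose: short fragmented transcripts mechanically inflate TTR, and that
artifact is part of what the measure is used to detect.

## Dependency networks

Vertices are lowercased surface forms (clitics such as `'s` keep their
own vertex); arcs are distinct (governor, dependent, relation) triples
weighted by occurrence; root and punctuation links never enter. Summary
statistics follow the conventions of classic network-analysis software
for directed networks with loops allowed: average degree 2m/n and
density 2m/n², with m the number of distinct arcs.

Betweenness, closeness and clustering are computed on the undirected
simple skeleton (directions and weights dropped, parallel arcs merged,
loops ignored): normalized shortest-path betweenness (divisor
(n−1)(n−2)/2), Wasserman–Faust per-component-scaled closeness, and the
local clustering coefficient (0 for degree < 2). The undirected choice
is deliberate: published per-vertex tables show clustering 1 for
low-degree function words, which is only attainable with undirected
neighbour-edge counting. These formulas are the package's contract and
are verified against an exhaustive shortest-path-enumeration oracle on
all small graphs in the test suite; published full-corpus vertex tables
are treated as data for the statistical layer, not as recomputation
targets, since the underlying corpora are access-restricted.

Rankings (weighted degree, cross-difference truncation) order by value
descending with ties broken by label ascending, for determinism. The
cross-difference of two networks keeps the arcs of the first whose key
is absent from the second, retains the first network's weights, and
restricts vertices to the retained arcs' endpoints.

## Statistical workflow

`compare_groups` runs Shapiro–Wilk per group, Levene's test with
mean-centred deviations (the SPSS convention — this choice reproduces
published Levene F values exactly), then a pooled-variance t-test when
Levene's p > 0.05 and Welch's otherwise. Cohen's d always uses the
pooled SD. The screening chain is Pearson (keep p < 0.05 and
|r| ≥ 0.100), then iterative VIF removal (drop the worst column while
any VIF ≥ 5; perfect collinearity gives an infinite VIF and is removed,
never an error). Stepwise selection uses the named tool's canonical
defaults — enter at partial-F p < 0.05, remove at p > 0.10 — since no
thresholds are published; standardized betas come from z-scored
variables, and per-predictor VIFs are recomputed on the final design.

Treating network vertices as independent observations in a t-test (as
the published workflow does for 30 function-word vertices) is
statistically questionable — vertices of one network are not independent
— and is reproduced here as-is for comparability, not endorsed.

## Synthetic treebank generator

The generator emulates the *shape* of picture-description speech corpora:
two groups of 150 single-speaker transcripts, ~10 utterances each, short
utterances including verbless fragments and phrase-only units. Sentences
are assembled from dependency templates — transitive SVO cores with
optional auxiliary, existential-*there* frames, copular predications,
determiner/possessive/adjective pre-modifiers, adpositional
post-modifiers, full and reduced relative clauses, mark-introduced
subordinate clauses, phrase- and clause-level coordination, disfluent
subject restarts (reparandum) — with content words drawn from a
bounded-Zipf lexicon over a fixed function-word inventory. Every
parameter of `SyntacticProfile` steers at least one index of the
catalogue, and every generated sentence is a validated single-rooted
tree. A single seeded generator is threaded through the whole corpus, so
identical (profile, seed) pairs regenerate byte-identical CoNLL-U.

The presets encode the documented group contrast: the AD-like profile
has more existential frames (0.45 vs 0.10 per root clause), copular
predications (0.22 vs 0.10), fragments (0.20 vs 0.05), repetitions
(0.12 vs 0.02) and heavier noun-phrase elaboration (adjective rate
0.65 vs 0.35, PP post-modifier rate 0.55 vs 0.25), and fewer subordinate
clauses (0.05 vs 0.45), relative clauses (0.04 vs 0.18) and clausal
coordinations (0.10 vs 0.35), with shorter target sentence length
(11.5 vs 14.5 tokens) and a steeper Zipf exponent (1.25 vs 1.05). These
defaults are calibration choices fixed so that the generated group MDD
means fall in the 2.5–2.7 band with an AD-below-HC gap of roughly 0.1–0.15
and a per-transcript SD near 0.2 — the regime reported for real
picture-description corpora — and so that the AD-like network
concentrates betweenness on function words. They are properties of the
generator, not claims about any clinical population.

What passing tests show: the pipeline's measurements are arithmetically
correct (oracle equivalence), and the generator's group contrasts are
recovered end-to-end with high replicate stability. What they do not
show: anything about real AD speech — the generator has no lexical
semantics, no topic structure, no acoustic or timing phenomena, no
severity gradient, and its independence assumptions (Bernoulli/Poisson
choices per slot) are far simpler than human production.

## Numerical and scale choices

- Random numbers: `numpy.random.default_rng` seeded explicitly
  everywhere; monotonicity checks reuse one seed across profile variants
  as a common-random-numbers device.
- Test problem sizes: the oracle sweeps use all tested connected graphs
  up to 8 vertices (betweenness/closeness/clustering), 1,000 random
  trees (MDD), 50 replicates at n = 200 (stepwise recovery) and 20
  replicates at 150 transcripts per group (direction recovery); these
  sizes give stable verdicts while keeping the default suite fast.
- Degenerate inputs: empty files, verbless fragments, constant feature
  columns, perfectly collinear predictors and zero-variance samples all
  have defined behaviour (error or flagged missingness) covered by
  tests.

## Known limitations

- The Stanford→UD relation mapping covers the labels needed by the index
  catalogue, not the full historical label inventory.
- Utterance segmentation uses terminal punctuation and line breaks as a
  proxy for prosodic/dialogue boundaries; true intonation-based
  segmentation is not recoverable from plain text.
- The CoNLL-U reader keeps only basic token lines; enhanced dependencies,
  multiword tokens and empty nodes are skipped (with warnings), as they
  carry no positional head usable for distance computation.
- Running a dependency parser is out of scope: the package consumes
  parses, and a parser adapter is the natural extension point.
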