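# Methods

This note documents the statistical and algorithmic choices behind
`painlex`, the parameters that matter, what the synthetic generators do and
do not emulate, and the places where a convention had to be fixed because
the field uses several.

## Tokenization contract

All counting — rates per 10,000 tokens, collocation windows, wildcard token
matching — runs over a single canonical tokenizer: Unicode-aware,
lowercase-folding, splitting on every non-alphanumeric character except
apostrophes internal to a word. Hyphens split ("back-pain" → "back",
"pain"), punctuation yields no tokens. Term normalisation in the lexicon
builder applies the same rule and rejoins with single spaces, so a corpus
token and a lexicon unigram are always directly comparable. Consequence:
token counts exclude punctuation, so rates per 10,000 tokens computed here
can differ slightly from tools whose denominators include punctuation
tokens. Character-length statistics are measured on the raw text in Unicode
code points, before tokenization.

Keyword document selection defaults to case-insensitive raw-substring
matching ("painful" contains "pain"), mirroring SQL `LIKE` extraction from
note databases; an exact-token mode is available via `substring=False`.

## Collocation and MI

Collocates are tokens within ±w of a node occurrence (w = 5 by default),
windows never crossing document boundaries. The association score is
span-adjusted pointwise mutual information in bits,
MI = log₂(O·N / (f_n·f_c·S)) with S = 2w — the Church–Hanks formulation as
implemented by corpus tools in this area. O = 0 maps to a −∞ sentinel and
is excluded from reports.

Counting convention: each collocate token *position* counts at most once,
attributed to its nearest node occurrence (ties to the earlier node). The
alternative — counting every (node, collocate-position) pair — can push O
above f_c when node occurrences cluster within a window of each other; the
position-unique rule keeps O ≤ f_c as an invariant while still letting a
node token inside another node's window count as a collocate of itself.
The brute-force oracle in the test suite implements the same definition
independently and is checked for exact agreement on random corpora.

Report filters are strict inequalities (O > 10, MI > 6 by default). The
MI cut-off is a parameter: published analyses in this area variously use
"> 3", "≥ 5" and "> 6"; the default here is the strictest of those, and
callers choose their own.

## Elbow threshold selection

Given the descending cosine-similarity curve of a seed term's top-k
neighbours (k = 100 by default; the curve beyond that is flat and only adds
noise), both axes are min-max normalised to [0, 1] and the knee is the
point at maximum perpendicular distance **below** the chord joining the
first and last points — the Kneedle construction for decreasing convex
curves. Signed (below-chord) rather than absolute distance matters: for a
knee past the curve's midpoint between two near-flat plateaus, the
absolute-distance criterion would select the last high-plateau point, which
sits *above* the chord, instead of the knee. Ties take the smallest rank.
A curve with no point below the chord (collinear or concave) has no knee;
the convention is elbow_rank = curve length, so that all but the final
point are retained.

Retention is strict: candidates must have similarity strictly greater than
the similarity at the knee, which excludes the knee point itself. The
construction is invariant to affine rescaling of the similarities, so raw
and normalised similarity scales give the same rank. Whether inclusive or
exclusive cuts, or raw or normalised coordinates, were used by any
particular published threshold is generally unstated; this package's
convention is documented here, not asserted as anyone else's.

Embedding-model hyperparameters (algorithm, size, window, min_count) are
provenance metadata recorded on the vector table; model training is out of
scope — tables are consumed in word2vec text format.

## Lexicon curation rules

* ≤2-token filter: terms of three or more tokens are rejected; they are
  mostly redundant with their two-token cores ("pain of jaw" vs "jaw
  pain").
* ≥4-character filter: applies to unigrams only. The exemption for
  multi-token terms is a deliberate design choice: without it every
  "<short anatomy> pain" bigram ("jaw pain", "hip pain") would be destroyed
  by its short first token.
* Misspellings harvested from embeddings are ordinary entries; there is no
  automatic spell correction, and nothing is flagged unless a source labels
  it.
* Licensed terminologies (UMLS, SNOMED-CT, ICD-10, MeSH) cannot be
  redistributed, so ontology-derived terms enter as flat term-list files
  under a documented input contract rather than via ontology parsing.
* Reviewer decisions are a formal file format (term, action, category)
  standing in for human judgment; removals require a category (ambiguous /
  not-pain / vague) and every decision lands in an audit trail from which
  the pre-review state is reconstructible.

A merged lexicon reports both its unique term count and its pre-dedup
multiset total, since "lexicon size including duplicates" is ambiguous
between the two readings.

Reference matching in evaluation is string-exact after the shared
normalisation by default. The head-credit mode additionally credits a
reference term containing a known head word (cramp, colic, ache, ...) as a
token or token suffix; it exists because curated ontologies often phrase
concepts as three-token descriptions whose pain-bearing head the lexicon
does capture. Reports always name their mode, and head-credit matches are
a superset of exact matches by construction.

## Pattern templates and wildcards

Template assignment matches tokens greedily against three gazetteers with
precedence head > anatomy > quality; a valid assignment binds exactly one
head slot. Single-token terms ending in a head are fused compounds; the
prefix binds as anatomy only if the anatomy gazetteer contains it (longest
head suffix wins, so "backache" binds "ache" rather than a shorter
competing head). Gazetteers are inputs: the package ships rules, not
inventories.

Wildcard search interprets `%x%` / `x%` / `%x` / `x` at the token level
(contains / prefix / suffix / exact), case-insensitively; `%` may only
anchor the pattern ends. A raw-substring mode reproduces character-level
SQL `LIKE` semantics across token boundaries for parity with
database-resident searches. Denominators are documents by default; a
document→patient grouping map switches the unit to patients, since cohort
percentages may be quoted either way.

## Synthetic study conditions

The corpus generator plants, exactly: a seed-term rate per 10,000 tokens
(default 30/10k, the order of magnitude seen for "pain" in clinical-note
collections), collocates at designed (O, f_c, side-bias) within a ±5
window, bigram modifiers ("chronic pain"), misspellings, and metaphorical
idiom mentions flagged with their document ids in the manifest. Exactness
comes from layout: every seed occurrence sits at the centre of its own
document, so windows cannot interact; planned collocates fill designated
in-window slots; marginal top-ups and misspellings go into seed-free filler
documents; filler text is drawn from a closed ~50-word vocabulary with
Zipf weights. The manifest records expected MI per planted collocate via
the same formula the analysis uses, and every manifest value is checked
against brute-force recomputation in the tests.

What this does *not* emulate: real clinical vocabulary breadth, sentence
structure, negation, section headers, or the skewed document lengths of
EHR systems. Passing tests demonstrate the *arithmetic* of the pipeline is
exact under controlled conditions, not that any particular rate or MI value
generalises to real notes.

The vector-table generator produces cosine curves with a high plateau
(0.90 → 0.75), a drop, and a gently sloping low plateau (from 0.25,
per-rank slope 0.3 of the rank pitch), plus uniform noise. Vectors realise
the target cosines exactly by construction (c·u + √(1−c²)·v with v ⊥ u).
`max_noise(profile)` gives the amplitude below which knee recovery is
guaranteed: the binding constraint is adjacent low-plateau ranks, giving
a bound of 0.9·min(range·(1−slope)/(2(n−1)), plateau-separation/2). At
the default geometry (24 neighbours) this is ≈ 0.008–0.01; recovery is
100% at zero noise and ≥95% just under the bound across planted ranks
3–20.

Problem sizes in tests and the acceptance script — 100 random ≤1,000-token
corpora for the oracle check, 50 seeded 4,000-token corpora for rate
recovery, 100 vector tables of 24 neighbours, a 565-term engineered
coverage fixture — were chosen so the exactness properties are exercised at
full strength while the whole suite runs in seconds.

## Numerical and degenerate-input conventions

* Ranking tie-breaks are deterministic everywhere: lexicographic on terms
  (cosine ranking, frequency profiles), O-descending-then-lexicographic for
  MI-ranked collocates.
* Zero vectors in a table sink to the bottom of cosine rankings rather than
  producing NaNs.
* A corpus with zero tokens raises on rate computation; an empty keyword
  selection returns an explicit empty result (n_docs = 0, stats None)
  rather than raising.
* Sampling uses a single stated RNG (`random.Random(seed)`); generators
  record their seed in output metadata and are byte-reproducible.
* Elbow analysis requires ≥3 points and a non-increasing curve;
  verification tolerance for "non-increasing" is 1e-12.

## Known limitations

* No negation/experiencer handling and no metaphor classification — idiom
  mentions are generated and labelled for future precision studies, but
  nothing classifies them.
* Ontology inputs are flat lists; no OBO/OWL traversal.
* The elbow convention (signed distance, strict retention, normalised
  coordinates) is one defensible choice among several; thresholds from
  other tools are not directly comparable.
* Table-level coverage numbers from restricted EHR corpora cannot be
  reproduced here; the package demonstrates the machinery on engineered
  fixtures with the same shape instead.
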