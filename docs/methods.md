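# Methods

## The coding problem and the model of the classification

The NOC 2016 is modelled as four code-indexed maps — broad categories
(1-digit), major groups (2), minor groups (3), unit groups (4) — with the
hierarchy defined purely by digit prefixes. Codes are strings throughout:
"0011" and "11" are different objects, and arithmetic on codes is never
performed. Each unit group carries a group title, example occupational
titles, and three descriptive fields (lead statement, main duties,
employment requirements). Two derived indexes are built on load: a title
index mapping normalized titles to unit-group codes, and a token
vocabulary with corpus frequencies over all titles, group names and
descriptions. The vocabulary doubles as the candidate pool for spelling
correction, which guarantees corrections land on searchable terms.

The on-disk format is a single CSV with one row per group at any level
(`level, code, name, example_titles, lead_statement, main_duties,
employment_requirements`), example titles separated by ";" within the
cell. Column names and delimiters are configurable (`DumpDialect`)
because real exports differ; the shipped default matches the package's
own writer, and `load(write(db)) == db` holds field-for-field. Official
tables sometimes print major groups as ranges ("01-05"); the loader
expands a range into one group per covered two-digit prefix, all sharing
the range's name, so that every unit group's three ancestors always
resolve.

## Text repair

All matching operates on normalized text: casefolded, trimmed, internal
whitespace collapsed. Tokenization replaces punctuation with spaces and
splits on whitespace. Symbol splitting (on "/", "-", punctuation) turns
compound answers like "Bartender/waiter" into ordered parts. The
stop-word list is a small fixed English list shipped as a data file and
overridable in configuration.

Stemming is a self-contained implementation of the classic five-step
suffix-stripping algorithm, with one revision: the y→i rule fires only
when the y is preceded by a consonant, so that "employers" → "employ" is
stable under re-stemming while "happy"/"happiness" still conflate.
Matching stems query and classification text exactly once each,
symmetrically, so the (known) non-idempotence of suffix stripping on
derivational chains ("environmental" → "environment" → "environ") cannot
produce asymmetric comparisons.

Noun extraction uses a deterministic heuristic tagger: a token counts as
a noun unless it is a stop word or carries a typical adjectival suffix
(-al, -ic, -ive, -ous, -ful, -less, -ing, -ed on tokens longer than five
characters); when nothing survives, the last token is returned, since
English job titles overwhelmingly end in their head noun ("agricultural
producer", "certified accountant"). The tagger is pinned by
configuration; no statistical model is involved, which keeps the pipeline
fully reproducible.

Spelling correction is token-wise Damerau–Levenshtein (substitution,
insertion, deletion, adjacent transposition; restricted/OSA variant) with
default maximum distance 2 — the distance that covers observed survey
errors like "constuction" (deletion) and "accontant" (deletion) as well
as transpositions. Among vocabulary words within range, the highest
corpus frequency wins; ties break lexicographically. A token already in
the vocabulary is never changed, and correction is applied before
stemming. Compound words are corrected per token after symbol splitting.

## Search strategies

The seven strategies are evaluated strongest-to-weakest and the cascade
stops at the first non-empty result. Their semantics are cumulative by
construction: *like* is character-substring containment (the string "may
be included anywhere in the associated text"), and each *near*/*any* tier
accepts the substring relation in addition to its own token condition — a
contiguous substring trivially contains every query token in order — so
the hit sets are provably nested (exact ⊆ like ⊆ near-same-order ⊆
near-different-order ⊆ any ⊇ weak) even when a substring match cuts
mid-token. *Minor exact* spell-corrects each query token against the
classification vocabulary and then compares token sequences, which also
makes it insensitive to punctuation inside official titles.

The default search scope is occupational titles plus group names at all
levels; a match against a level 1–3 group name yields one candidate per
unit group beneath it (this is how a bare "TEACHER" reaches the teaching
unit groups through the minor-group name). The descriptive fields join
the scope only for the weak strategy and in the filter, mirroring the
design in which descriptions are a fallback, not a primary target.

A deliberately naive quadratic scanner (`brute_force_match`) re-implements
the same semantics with plain loops and serves as the independent oracle
in the test suite; it is never used by the pipeline.

## Pipeline and filtering

Stage 1 runs the cascade on the raw job title (industry if no title).
Stage 2, on failure, retries repair variants in order: split-title parts
combined with the industry (first part has priority), parts alone,
stop-word removal, stemmed matching, noun extraction. Stage 3 searches
the industry, whole and then split, ranking split parts by the frequency
of the part in the titles of the unit groups it matched. Stage 4 applies
spelling correction to the title tokens (never to the industry) and
re-searches, including the corrected nouns. A record that still matches
nothing is emitted explicitly unassigned — never dropped and never an
exception — so production rate is computable from output alone.

When a stage yields several unit groups, seven ordered rules narrow them:
job-title tokens against (1) broad-category, (2) major-group, (3)
minor-group names and (4) unit-group titles; industry tokens against (5)
the candidates' occupational titles, (6) split-industry parts ranked by
keyword frequency in the candidates' titles, (7) the unit-group
descriptions. Rule matching is stemmed-token containment, which is what
lets singular "teacher" match plural group names. A rule that matches no
candidate is skipped (survivor set unchanged, recorded in the trace); a
matching rule restricts to its matching candidates, so narrowing is
monotone. Keyword frequency counts non-overlapping occurrences of the
normalized keyword. Ties surviving all rules break by ascending code — a
stable, documented rule chosen over the alphabetical-last ordering used
early in the original development, which that project itself identified
as a source of lost matches. The direction is configurable. Without an
industry, rules 5–7 are skipped.

Generation presets g0–g4 disable, cumulatively, the updates each
development generation introduced (g0: four strategies, no splitting, no
correction, no hierarchical filter; g1 adds splitting/correction/nouns
and the full cascade; g2 industry splitting; g3 title+industry
combinations; g4 frequency ranking and the hierarchical filter).

## Evaluation

Match level is the longest common digit prefix (0–4) of assigned and gold
codes; "accurate at position k" means level ≥ k, which makes k-digit
accuracy non-increasing in k structurally. The accuracy denominator is
all records, not only the coded ones (the published generation-0 figures
divide by 566, not 529); an unassigned record counts as level 0.
Transition matrices between two variants are 5×5 counts over (level under
the earlier variant, level under the later), diagonal excluded; column
sums above a level are gains, row sums are losses. The printed
generation-comparison tables label rows with the later variant, but their
accompanying gains/losses arithmetic only balances when rows index the
earlier variant; this package fixes that convention (rows = earlier) and
the published cell values then reproduce the quoted 88 gains / 78 losses
and the +10/+11/+12/+10 nets exactly.

## Synthetic data

The in-package fixture is the published miniature of the classification:
the 10 broad categories, the senior-management branch (00/001/0011–0016)
and the education-services branch (40/403/4031–4033), names verbatim,
each unit group carrying its group title as its sole example title.

The random generator builds hierarchically consistent classifications
from a curated occupational vocabulary (role nouns, modifiers, sector
and filler words). Two design constraints make recovery experiments
well-posed: generated titles are globally unique modifier+role pairs, so
zero-noise inputs have exactly one exact match; and distinct vocabulary
words are pairwise ≥ 3 Damerau–Levenshtein edits apart, so a single-typo
token has a unique nearest vocabulary word and correction cannot be
ambiguous. Title collisions across unit groups — which do occur in the
real classification — are injected only through the explicit
`collision_rate` switch. Default generator size is 4 major groups × 3
minor × 5 unit groups × 4 example titles (60 unit groups), large enough
to exercise every strategy and filter rule while keeping oracle-
equivalence sweeps fast.

Noise injection emulates the pathologies observed in real survey answers:
per-record typo probability with a bounded number of random character
edits (substitution/transposition/deletion/insertion at letter positions,
so word boundaries survive), slash compounds joining a title from another
unit group (the gold code stays with the first part), adjective prefixes
drawn from words deliberately outside the classification vocabulary
("certified", "licensed", …), and whole-string upper-casing. Defaults
(typo 0.15, compound 0.10, adjective 0.15, case 0.25, one edit) represent
moderately dirty free text. Everything is deterministic in the seed.

What the synthetic experiments show — and do not. Exact recovery at zero
noise and ≥ 90% four-digit accuracy under a forced one-edit typo per
title validate the machinery: the cascade order, the correction
geometry, and the filter's determinism. They do not estimate accuracy on
real survey data, where titles collide across unit groups, spelling
errors exceed one edit, and the mapping from colloquial titles to
official ones is genuinely ambiguous; the published benchmark of the
original development (55–59% four-digit accuracy on 566 real records) is
the realistic reference point, and reproducing it would require the full
classification dump and a manually coded data set, neither of which ships
with the package.

## Numerical and degenerate-input choices

Edit distance uses the restricted (optimal string alignment) variant with
an early-exit bound for vocabulary scans. Empty queries and empty
candidate sets are domain errors; an empty dump stream is a parse error;
a batch never aborts on a per-record failure. Spell-correct ties break by
frequency then lexicographic order; filter ties by ascending code;
split-part priority is left-to-right, first non-empty wins. Problem sizes
in the shipped tests and acceptance script (60-unit classifications,
200-query oracle sweeps, 500-record recovery batches) were chosen as the
smallest sizes at which every strategy, filter rule and pipeline stage is
exercised with comfortable statistical margin.
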