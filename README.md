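# occucoder

Rule-based automated occupation coding to the Canadian National
Occupational Classification (NOC 2016).

Health researchers, insurers and statistical agencies routinely collect
occupation as free text ("What is your job title?" / "What industry do you
work in?") and must translate the answers into standard codes before any
analysis. Manual coding is reliable but slow — days of expert time per few
hundred titles — and the input text is short, misspelled and irregular
("CONSTUCTION", "Bartender/waiter", "certified accontant"). `occucoder`
automates this for the NOC 2016, a four-level hierarchy of 10 broad
occupational categories, major groups, minor groups and 500 four-digit
unit groups, where the hierarchy is encoded purely in digit prefixes
(unit group 0011 sits under minor group 001, major group 00, category 0).

## Method

Each record is coded by a cascade of seven search strategies, strongest
first, over the classification's occupational titles and group names:

| order | strategy | accepts when |
|---|---|---|
| 1 | exact | normalized query equals the text |
| 2 | minor exact | exact after spell-correcting each query token |
| 3 | like | query is a contiguous substring |
| 4 | near (same order) | all query tokens occur, in order |
| 5 | near (different order) | all query tokens occur, any order |
| 6 | any | at least one query token occurs |
| 7 | weak | at least one query *noun* occurs (scope widens to unit-group descriptions) |

The cascade stops at the first strategy with hits. When the raw job title
finds nothing, the pipeline escalates through deterministic text repair
(symbol splitting with title+industry combinations, stop-word removal,
Porter stemming, noun extraction), then the industry description (whole,
then split on symbols with parts ranked by keyword frequency), and finally
token-wise spelling correction (Damerau–Levenshtein, max distance 2,
candidates drawn from the classification's own vocabulary, highest corpus
frequency wins). If several unit groups remain, a seven-rule hierarchical
filter narrows them — job title against category/major/minor/unit names,
then industry against titles, split-industry keyword frequency, and
unit-group descriptions — with remaining ties broken by ascending code.

Coding runs are scored the way autocoding studies report results:
*production rate* (fraction of records assigned any code), *k-digit
accuracy* (fraction of all records whose assigned code shares a ≥ k-digit
prefix with the manually assigned gold code), and 5×5 *transition
matrices* of match levels between two algorithm variants, whose column and
row sums decompose a net accuracy change into gains and losses.

## Worked example

```python
import occucoder as oc

db = oc.build_inpaper_fixture()          # miniature NOC shipped in-package
result = oc.code_record(
    oc.CodingInput(job_title="TEACHER", industry="EDUCATION"), db)
print(result.assigned, result.strategy.name, result.candidate_codes)
print(result.filter_trace.surviving_codes_per_step)
```

prints

```
4031 LIKE ('4031', '4032', '4033')
((3, ('4031', '4032', '4033')), (4, ('4031', '4032')))
```

"teacher" is not itself an occupational title in the fixture, but the
like-search finds it inside the minor-group name *secondary and elementary
school teachers and educational counsellors*, yielding three candidate
unit groups. The filter's minor-group rule (step 3) keeps all three, the
unit-title rule (step 4) narrows to the two teaching unit groups (4031
secondary school teachers, 4032 elementary school and kindergarten
teachers), and the ascending-code tie-break selects 4031.

The same flow works from the shell:

```shell
occucoder fixtures --out fx/ --seed 1 --n-inputs 100
occucoder code --noc fx/noc_synthetic.csv --input fx/inputs_synthetic.csv \
               --output coded.csv
occucoder eval --coded coded.csv
```

`occucoder code` accepts `--generation g0` … `g4` presets that disable the
repair stages later development generations introduced, so the iterative
benchmarking design can be reconstructed on any data set.

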