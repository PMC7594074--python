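# fairmi — FAIR maturity indicators for life-science datasets

`fairmi` implements a semi-automated workflow for assessing how **F**indable,
**A**ccessible, **I**nteroperable and **R**eusable a dataset is. It is aimed
at data stewards, repository curators and bioinformaticians who want a
concrete, reproducible answer to "how FAIR is this dataset?" — indicator by
indicator, without collapsing everything into a single score.

The workflow mirrors how a researcher actually finds data: given the
keywords they searched with and the accession of the dataset they settled
on, the tool gathers three kinds of evidence —

1. the **dataset metadata** from the repository (six metadata dialects:
   ArrayExpress, Gene Expression Omnibus, eNanoMapper, caNanoLab, ChEMBL,
   NanoCommons, plus a generic fallback),
2. the repository's **registry-of-repositories record** (re3data-style:
   DOI badge, availability policy, license), and
3. a **retrieval result** (HTTP status + protocol) and a manual
   searchable-resource flag —

and scores the 15 FAIR sub-principles F1–R1.3. Thirteen indicators are
evaluated; I2 and R1.3 are carried as explicit *not assessed* placeholders.

## Scoring rules

| Indicator | Rule | Values |
|---|---|---|
| F1 | registry shows a persistent-identifier (DOI) badge | 0/1 |
| F2 | fraction of search keywords found in the metadata text | m/n in [0,1] |
| F3 | metadata contain the dataset accession (exact, case-insensitive) | 0/1 |
| F4 | dataset title indexed in a dataset search engine (manual flag) | 0/1 |
| A1 | HTTP request returned 200 | 0/1 |
| A1.1, A1.2 | retrieval protocol is HTTP(S) | 0/1 |
| A2 | registry states a data availability policy | 0/1 |
| I1 | metadata are well-formed XML or JSON | 0/1 |
| I3 | metadata reference *other* datasets | 0/1 |
| R1 | metadata carry attributes beyond the search keywords | 0/1 |
| R1.1 | registry fills both license name and license URL | 0/1 |
| R1.2 | provenance fields {authors, email, title}: all → 1, some → 0.5, none → 0 | 0/0.5/1 |
| I2, R1.3 | not assessed | — |

Each score also records its retrieval mode (automatic / manual /
not assessed), which the **FAIR balloon plot** renders as circle / diamond /
cross, with mark size = score and color = FAIR category (Findable blue,
Accessible red, Interoperable green, Reusable orange).

## Worked example

```sh
fairmi fixtures --write fx --seed 7          # six synthetic use-case bundles
fairmi assess --config fx/config.yaml --offline fx --out matrix
fairmi plot matrix.csv -o balloon.svg
```

which prints

```
wrote fixtures for 6 use cases; config at fx/config.yaml
assessed 6 use case(s); wrote matrix.csv and matrix.json
wrote balloon.svg
```

`matrix.csv` holds one row per use case with 15 score columns and 15 mode
columns. The first data line,

```
Parkinsons_AE,0.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0,1.0,,0.0,1.0,1.0,1.0,,manual,...
```

reads: for the Parkinson's-disease ArrayExpress use case, metadata carry no
DOI badge (F1=0) but contain all search keywords (F2=1) and the accession
(F3=1), the dataset is indexed (F4=1), retrieval was HTTP 200 (A1 family=1),
ArrayExpress states an availability policy (A2=1), the metadata are
structured (I1=1), reference no other dataset (I3=0), carry rich attributes
(R1=1), a license (R1.1=1) and full provenance (R1.2=1); the two empty
cells with mode `not_assessed` are I2 and R1.3. Across the six bundled use
cases, only ChEMBL has the DOI badge, only ArrayExpress a policy, only
caNanoLab and ChEMBL cross-references, only the GEO case is missing from
the dataset search engine, and R1.2 is 1 / 0.5 / 0 for ArrayExpress /
ChEMBL / the rest.

The same matrix is available programmatically:

```python
import fairmi
rows = []
for profile in fairmi.builtin_profiles():
    b = fairmi.generate_evidence(profile, seed=7)
    rows.append(fairmi.assess_use_case(b.query, b.metadata, b.registry,
                                       b.retrieval, b.f4_flag))
matrix = fairmi.build_matrix(rows)
print(matrix.to_dataframe())
```

Qualitative (traffic-light) assessments from manual FAIR reviews can be
imported too: `fairmi import-qualitative table.csv -o converted` maps
"complies completely" → 1, "just about/maybe not" → 0.5, "fails to comply"
→ 0 and leaves "unclear" cells blank in the plot.

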