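# brevity

Statistical tests for **Zipf's law of abbreviation (ZLA)** — the tendency for
frequently used signals to be shorter — in repertoire-based animal
communication, built for annotated birdsong but applicable to any system
where tokens can be classified to types, timed, and attributed to
individuals.

Testing ZLA in song is harder than in text. Repertoires are small, so even a
perfect duration–frequency concordance may be weak evidence. Individuals in
one population can use different, partly overlapping repertoires, so
population-level correlations can arise without any individual economizing.
And song is learned: two birds showing the same pattern may both have copied
it from one tutor, so birds are not independent replicates. `brevity`
implements an individual-level permutation test built around these
constraints, plus the tooling to synthesize results across populations,
compare them with written language, and validate the whole pipeline on
synthetic data with known ground truth.

## The statistic and its null

Let $a_{ijk}$ be the log duration of instance $i$ of phrase type $j$ sung by
bird $k$, $f_{jk}$ the number of times bird $k$ produced type $j$, and
$\bar a_{jk}$ the mean of bird $k$'s log durations for type $j$. For each
bird, $\tau_k$ is Kendall's $\tau_B$ (tie-corrected in both margins) between
the $\bar a_{jk}$ and $f_{jk}$ over the bird's own repertoire of $n_k$
types. Because $\tau_k$ has null variance

$$v_k = \frac{2(2n_k+5)}{9\,n_k(n_k-1)},$$

birds with larger repertoires are more informative, and the population
statistic is the inverse-variance weighted mean
$\bar\tau = \sum_k \tau_k/v_k \big/ \sum_k 1/v_k$. On the
$(\bar\tau+1)/2$ scale this is the probability that, for a random bird and a
random pair of its phrase types, the longer type is the more frequent one;
ZLA predicts $\bar\tau < 0$.

The null distribution respects learned song structure. Each type's
population-expected log duration $\bar a_j$ is the REML intercept of an
intercept-only one-way random-intercept model over birds (birds that sing
the type more often get more weight). The deviation matrix
$D[j,k] = \bar a_{jk} - \bar a_j$ captures how each bird renders each type.
A replicate permutes the $\bar a_j$ among types — identically for every
bird, preserving who-sings-what and how often — and adds or subtracts the
whole deviation matrix with equal probability. Per-bird $\tau$ values on the
permuted matrix recombine with the same weights into one null draw
$\bar\tau_p$; the one-tailed p-value is the proportion of draws with
$\bar\tau_p \le \bar\tau$. The $\alpha$-quantile of the null is the
**detection threshold**: how strong a concordance this population's
repertoire structure could ever certify as significant.

Durations are log-transformed by default: among-bird spread in raw durations
grows with the mean, and permuting raw durations would shuffle large
deviations onto short types, biasing the null. Median-based centers
(`center="median"`) and raw-scale analysis (`scale="raw"`, discouraged for
durations) are available.

## Worked example

Simulate a 10-bird population with moderate ZLA (copula effect −0.4) and
test it:

```sh
brevity simulate --seed 11 --effect -0.4 --output demo.csv
brevity test --input demo.csv --permutations 2000 --seed 7
```

prints (abridged):

```
tau_bar               -0.1967
p_individual           0.0125
tau_pop               -0.1518
p_pop                  0.144
detection_threshold   -0.1483
```

The individual-level weighted mean concordance is −0.197: for a random bird
and phrase pair, the longer phrase is the more frequent one with probability
(1 − 0.197)/2 ≈ 0.40. Only 1.25% of null replicates were as negative, so
the pattern is significant at α = 0.05 — consistent with the detection
threshold of −0.148, which the observed −0.197 clears. The population-level
concordance (−0.152, p = 0.144) is weaker: individual-level structure need
not show at the pooled level, which is exactly why the test works per bird.

Cross-population synthesis uses a per-population table (see
`brevity.load_population_table()` for a built-in 11-population example):

```python
>>> import brevity as bv
>>> effects = [bv.PopulationEffect(r.population, r.species, r.tau_bar,
...                                r.detection_threshold, r.total_phrase_types)
...            for r in bv.load_population_table().itertuples()]
>>> m = bv.meta_tau(effects)
>>> round(m.intercept, 3), round(m.se, 3), round(m.p_one_tailed, 3)
(-0.071, 0.024, 0.012)
>>> bv.detection_regression(effects, predict_at=m.intercept)["predicted"]
193.93...
```

The expected individual-level concordance across these populations is
−0.071 (significantly negative: weak but consistent ZLA), and a population
showing that strength of concordance would need a repertoire of roughly 194
phrase types before the test could call it significant.

The human-language baseline (`brevity text *.txt`) computes the same
concordance between word length and frequency in plain-text documents and
pools documents as if they were individuals.

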