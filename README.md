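# adstar

Bayesian structured additive regression (STAR) for estimating the effect of
Asian dust storm (ADS) episodes on daily, district-level counts of
children's respiratory clinic visits — with a synthetic-data generator that
reproduces the statistical structure of the (restricted) insurance-claims
data, so the whole pipeline can be exercised and validated end to end.

The package is aimed at environmental epidemiologists and biostatisticians
working with episodic air-pollution exposures and small-area count data:
it classifies study days into exposure windows around dust-storm episodes,
fits a spatiotemporal Poisson model by MCMC, and reports effects the way the
disease-mapping literature does (percent changes with credible intervals,
district relative rates, posterior-probability maps).

## Model

Daily visit counts $Y_{st}$ in district $s = 1,\dots,S$ on day
$t = 1,\dots,T$ are Poisson with mean $\mu_{st}$ (optionally Poisson-gamma
for overdispersion, $\mathrm{Var}(Y_{st}) = \phi_s \mu_{st}$) and

$$
\log \mu_{st} = \alpha + \delta\,\mathrm{DOW}_t + \beta\,\mathrm{DSI}_t
 + \gamma\,\mathrm{PM}_t + f(\mathrm{TP}_t) + f(T_t)
 + u_s + \eta_s + \log(\mathrm{pop}_s),
$$

where

- **DOW** — six day-of-week indicators (Sunday is the reference);
- **DSI** — the dust storm index: indicators for ADS event days, post-ADS
  days (the 7 days after an episode's last day) and other days, with
  pre-ADS days (the 7 days before an episode's first day) as reference.
  When the post-window of one episode overlaps the pre-window of the next,
  the overlapping days count as event days;
- $\gamma$ — linear effect of same-day PM₁₀ (µg/m³), reported per
  10 µg/m³;
- $f(\mathrm{TP}_t), f(T_t)$ — cubic B-spline (P-spline) smooths of daily
  mean temperature and calendar time with second-order random-walk
  penalties;
- $u_s \sim N(0, \sigma^2_u)$ — exchangeable (unstructured) district
  effects; $\eta_s$ — intrinsic conditional autoregressive (CAR) effects on
  the district adjacency graph, with conditional mean equal to the
  neighbour average and conditional variance $\sigma^2_s / N_s$;
- all variances carry IG(0.001, 0.001) hyperpriors.

Sampling is Metropolis-within-Gibbs over parameter blocks with IWLS
(iteratively weighted least squares) Gaussian proposals centred at each
block's conditional mode, plus conjugate inverse-gamma variance updates.
The default schedule runs 22,000 iterations, discards 2,000 and keeps every
20th draw (1,000 retained).

Reported summaries: percent changes $100(e^b - 1)$ with 95% credible
intervals (significant if the interval excludes zero on the coefficient
scale), district relative rates $RR_s = e^{\eta_s}$ classified LOW / HIGH /
NEUTRAL by whether 80% of the posterior mass of $RR_s$ falls below / above
one, and the structured variance share
$\rho = 100\,\sigma^2_s / (\sigma^2_u + \sigma^2_s)$.

## Worked example

```python
from adstar import StarPoissonRegression, simulate_dataset
from adstar.model import dataset_to_Xy

ds = simulate_dataset(seed=1)          # 12 districts x 730 days
X, y = dataset_to_Xy(ds)
model = StarPoissonRegression(adjacency=ds.adjacency,
                              iterations=2200, burnin=200, thin=20,
                              random_state=1001).fit(X, y)
print(model.effects_.round(2).to_string(index=False))
print(f"rho = {model.rho_:.2f}%")
```

```
           effect  percent  lower  upper  significant
   ADS event days    -2.67  -3.08  -2.34         True
    Post-ADS days     3.29   3.03   3.62         True
       Other days     0.53   0.29   0.73         True
PM10 per 10 ug/m3     1.20   1.17   1.23         True
rho = 99.05%
```

The generator's true effects are −2.97% (event days), +3.38% (post-ADS
days), +0.45% (other days) versus the pre-ADS week, and +1.18% per
10 µg/m³ of PM₁₀, with a true structured variance share of 98.4% — each
recovered within posterior uncertainty.  `model.district_rr_` holds the
per-district relative rates and their 80%-posterior classification.

The same pipeline is scriptable from the shell:

```sh
adstar simulate --seed 1 --years 2 --out-dir data/
adstar classify-windows --out labels.csv            # bundled 1997-2007 events
adstar fit --counts data/counts.csv --environment data/environment.csv \
           --events data/events.csv --adjacency data/adjacency.tsv \
           --population data/population.csv --out draws.npz
adstar summarize --draws draws.npz --out-dir summary/
adstar report --draws draws.npz --out-dir summary/   # trace plots
```

## Package layout

- `adstar.windows` — exposure-window expansion and day classification
- `adstar.design` — fixed-effect design, offsets, observation layout
- `adstar.smoothers` — P-spline bases and RW2 penalties
- `adstar.spatial` — intrinsic CAR structure matrix and full conditionals
- `adstar.mcmc` — the block sampler and draw archives
- `adstar.model` — `StarPoissonRegression`, the scikit-learn estimator
- `adstar.summaries` — percent changes, relative rates, classifications
- `adstar.synthetic` — ground-truth data generator
- `adstar.io`, `adstar.cli` — file formats, bundled fixtures, CLI
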