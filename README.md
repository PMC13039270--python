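# guildgam

Hierarchical negative-binomial GAMs for guild-level insect richness from
Malaise-trap surveys: feeding-guild assignment, spatiotemporal modelling,
phenophase and host–parasitoid synchrony estimation, and habitat-scenario
prediction — with a seeded synthetic-survey generator so the whole pipeline
is testable without any data download.

## The problem

Nationwide Malaise-trap networks with DNA metabarcoding yield weekly counts
of species (OTUs) per trap. Grouping taxa into six feeding guilds —
phytophages, predators, saprophages, and a parasitoid guild attached to each
— turns this avalanche of taxa into a tractable picture of how trophic
layers move through space and season. The scientific questions are: how much
do host and parasitoid guilds overlap in space, how synchronised are they in
time (do parasitoid richness peaks trail their hosts', and by how many
weeks?), and which climate and habitat variables drive the patterns.

## The model

Guild-level weekly richness $y_{itg}$ at site $i$, week $t$, guild $g$ is
modelled as negative binomial with a two-level linear predictor:

$$\eta_{it} = f_s(S_t) + f_T(T_{ti}) + f_P(P_{ti}) + \tau(X_i, Y_i)$$

$$y_{itg} \sim \mathrm{NB}\!\left(\exp\Big(\textstyle\sum_h \beta_{hg} x_{ih}
  + f_{Sg}(S_t) + f_{Tg}(T_{ti}) + f_{Pg}(P_{ti}) + \tau_g(X_i,Y_i)
  + \mu_{ig} + \gamma_g + \eta_{it} + o_{it}\Big),\ \theta\right)$$

where $f_s, f_{Sg}$ are cyclic cubic splines of week (k = 6, period 52, so
seasonal curves close smoothly over the year boundary), $f_T, f_P, \tau$ are
thin-plate regression splines (k = 6) of temperature, precipitation and
space, $\beta_{hg}$ are guild × habitat-cover random slopes, $\mu_{ig}$
trap × guild random effects, $\gamma_g$ guild random intercepts, and
$o_{it} = \log(\text{exposure days}/7)$ an effort offset. Guild-level
smooths share their wiggliness smoothing parameter with the corresponding
global smooth; a second penalty on each smooth's null space (the *double
penalty*) lets whole terms be shrunk out of the model. Fitting is penalized
IRLS with extended Fellner–Schall REML updates of all smoothing parameters
and a profiled NB dispersion; uncertainty comes from the Gaussian
coefficient posterior $N(\hat\beta, (X^TWX + S_\lambda)^{-1})$.

Phenophases are read from each guild's seasonal trend (predicted along the
cross-site average temperature curve): start = first week reaching
$SR_{min} + 0.1\,SR_{max}$, peak = week of $SR_{max}$, end = last week at
the threshold; host–parasitoid lags are differences of paired peak weeks.

## Worked example

```sh
guildgam simulate --out sim --seed 2          # synthetic 200-site survey
python - <<'PY'
import pandas as pd
df = pd.read_csv("sim/richness.tsv", sep="\t")
df[df.week.between(14, 43)].to_csv("season.tsv", sep="\t", index=False)
PY
guildgam fit --data season.tsv --out model.json --theta 5
guildgam phenophase --model model.json --data sim/climate.tsv \
    --draws 200 --seed 1 --out phen
```

The fit prints per-term effective degrees of freedom, e.g.

```
fit: theta=5.000 deviance=33628.4 converged=True
global_season        4.04
global_precip        0.00
guild_season        21.67
habitat             13.44
site_effect        758.23
...
```

— precipitation (simulated with no effect) is penalised out (EDF ≈ 0) while
seasonal and habitat terms carry the signal. `phen/lags.tsv` then holds the
recovered host–parasitoid peak lags with 95% credible intervals:

```
host        parasitoid              host_peak  parasitoid_peak  lag_weeks  lag_lo  lag_hi
phytophage  phytophage_parasitoid   24.0       25.0             1.0        1.0     2.0
predator    predator_parasitoid    22.0       27.0             5.0        5.0     6.0
```

matching the generator's configured lags (1 week for phytophages, 5 for
predators and saprophages). `guildgam scenarios --paper-defaults` and
`guildgam predict --grid ...` give counterfactual habitat responses and
spatial richness maps from the same model file.

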