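# fptargets

Target setting for family-planning programmes: converting
**demand-satisfied (DS)** goals into actionable **modern contraceptive
prevalence (mCPR)** targets with the **accelerated transition (AT)**
method.

## The problem

SDG indicator 3.7.1 tracks the proportion of women of reproductive age
whose need for family planning is satisfied with modern methods.  A
widely used benchmark, *DS75*, asks every country to reach at least 75%
demand satisfied by 2030.  DS is a ratio — modern prevalence over total
demand (modern + traditional prevalence + unmet need) — so a DS goal
does not directly tell a programme how many additional users of modern
contraception it must reach.  Translating DS goals into mCPR targets,
and thence into user counts, is what makes them actionable.

## The method

Let `mod_t` be mCPR and DS_t demand satisfied under a *business as
usual* (BAU) projection, and let `t*` be the earliest year DS reaches
the target (capped at 2100).  For a country with `t*` beyond the goal
year, the AT method assumes the whole contraceptive-use transition —
prevalence *and* demand together — must run faster by the factor

    rel_accel = (t* − t_current) / (goal − t_current),

and adopts as the mCPR target for the goal year the BAU mCPR at `t*`:

    tmod = mod_{t*},      gap = tmod − mod_{t_current}.

The gap times the number of married/in-union women of reproductive age
(MWRA) gives the additional users required.  The demand-based (DB)
comparator instead holds demand on its BAU path and sets
`tmod_DB = 0.75 × demand_goal`; because accelerating modern use pulls
demand up with it, the DB target understates the need whenever demand
is still growing — the AT target dominates it for every country that
attains the DS target with growing demand.

BAU trajectories come from a deterministic one-country transition
model: total prevalence is logistic in time, the modern share of use is
logistic in time, and unmet need is a log-odds-linear fraction of
non-users, fitted to sparse survey series by penalised nonlinear least
squares (see `docs/methods.md`).

## Worked example

```python
from fptargets import ATConfig, STYLIZED_LATE_TRUTH, assess_country, db_target, project

config = ATConfig()  # DS75 by 2030, assessed from 2019, cap 2100
bau = project(STYLIZED_LATE_TRUTH, "Stylized", 2019, 2100)
at = assess_country(bau, config, mwra=5_000_000)
db = db_target(bau, config)

print(f"DS75 target year (t*):     {at.t_star} (capped: {at.capped})")
print(f"relative acceleration:     {at.rel_accel:.2f}")
print(f"AT target mCPR for 2030:   {at.target_mcpr * 100:.1f}%")
print(f"mCPR gap:                  {at.mcpr_gap * 100:.1f} percentage points")
print(f"additional users needed:   {at.users_gap / 1e6:.2f} million")
print(f"DB target mCPR for 2030:   {db.db_target_mcpr * 100:.1f}%")
```

prints

```
DS75 target year (t*):     2051 (capped: False)
relative acceleration:     2.91
AT target mCPR for 2030:   54.1%
mCPR gap:                  34.2 percentage points
additional users needed:   1.71 million
DB target mCPR for 2030:   45.2%
```

Under business as usual this stylized country reaches DS75 only in
2051, so its transition must run 2.9× faster to get there by 2030; doing
so means raising mCPR from about 20% to 54.1% — 1.71 million additional
users for 5 million MWRA.  The demand-based target (45.2%) is lower
because it ignores the demand growth that accompanies an accelerated
transition.

The same pipeline is available from the shell:

```sh
fptargets simulate --scenario mixed --n 10 --seed 7 --out-survey survey.csv --out-truth truth.csv
fptargets fit --survey survey.csv --out params.csv
fptargets assess --survey survey.csv --out results.csv
fptargets summarize            # headline counts of the packaged assessment table
```

## The packaged DS75 assessment table

`fptargets.load_table1_fixture()` returns the published 50-country DS75
assessment (countries needing acceleration, ordered by target year,
with their target mCPRs, gaps, user counts and accelerations).  The
country-specific targets in it derive from full Bayesian model fits to
the UN survey compilation and are served verbatim as printed inputs;
the acceleration column is a pure function of the target years and is
recomputed and cross-checked by this package.

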