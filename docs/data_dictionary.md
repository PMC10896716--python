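# Data dictionary

## Panel tables (`easidemand simulate` / `HouseholdPanel.write_csv`)

`households.csv` — one row per household-wave
| column | meaning |
|---|---|
| hh | household id |
| wave | survey wave (1-based) |
| cluster | enumeration-cluster id |
| stratum | sampling stratum (group of clusters) |
| urban | 1 = urban |
| nonfood_value | weekly non-food expenditure, US$ PPP |
| weight | household sampling weight |

`roster.csv` — one row per member: `hh`, `member`, `age` (years), `sex`
(`m`/`f`).

`records.csv` — one row per consumed item per household-wave
| column | meaning |
|---|---|
| hh, wave | keys |
| group | food group name |
| item | item name within the group |
| quantity | kg (or litre) consumed over the 7-day recall |
| value | US$ PPP value of that quantity |
| source | purchase / own_production / gift |

`composition.csv` — per food group, nutrient contents per 100 g (see
`easidemand.nutrients.NUTRIENTS` for the column list and units).

## Prepared observations (`prepare` / `PreparedData.to_frame`)

One row per household-wave: ids (`hh`, `wave`, `cluster`, `stratum`),
`lnx` (log weekly total expenditures), `x_week`, `ae` (adult
equivalents), `quartile` (Q1–Q4 by daily per-AE expenditures),
`stone_avg` (average-share Stone index), and per food group `g`:
`w_<g>` budget share, `lnp_<g>` log Fisher group price index,
`nbr_<g>` leave-one-out neighbour log price, `price_<g>` group price
level (US$/kg), `qty_<g>` weekly kg; `w_numeraire`; shifters `z_*`
(log_size, urban, head_age, wave dummies) and cluster means `cm_*`.
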