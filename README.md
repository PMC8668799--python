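# trygen

Generation and evaluation of hourly **test reference years (TRYs)** for
dynamic climate simulation in controlled-environment facilities (ecotrons).

From a multi-decade hourly station record and an ensemble of regional
climate-model projections, the package:

1. quality-controls, gap-fills and calendar-normalizes the station record
   (`trygen.station`);
2. converts ensemble model output (including specific-humidity members and
   sub-daily pressure) to smoothed 365-day climatologies and computes
   additive ensemble-mean **climate signals** per RCP scenario by the
   delta-change method (`trygen.ensemble`);
3. builds scenario reference climatologies and assembles an 8,760-hour TRY
   by greedy rank-scored resampling of 10–30-day historical weather
   segments, with linear transition smoothing and ozone/CO2 rescaling to
   scenario targets (`trygen.builder`);
4. adapts the TRY to facility limits: temperature/humidity clipping,
   radiation→PPFD conversion and compression, ozone treatment gradients and
   slew-limited 1-minute setpoint ramps (`trygen.chamber`);
5. evaluates results with climate extreme indices (TN10p … WSDI), kernel
   density estimates and prescribed-vs-measured deviation statistics
   (`trygen.evaluation`).

`trygen.fixtures` provides seeded synthetic inputs (station record, CO2
record, mock model ensemble with injected climate signals, noisy facility
logs) so the entire pipeline is testable offline.

## CLI

```sh
trygen gen-fixtures --seed 0 --years 30 --out data/
trygen build-signal --ensemble-file data/ensemble.csv --scenario rcp85 --out out/
trygen build-try --station-file data/station.csv --co2-file data/co2.csv \
    --signal-file out/signal_rcp85.csv --scenario rcp85 --out out/
trygen adapt-chamber --try-file out/try_rcp85.csv --treatment high --minutes --out out/
trygen indices --try-file out/try_rcp85.csv --station-file data/station.csv --out out/
trygen evaluate --prescribed-file p.csv --measured-file m.csv --out out/
```

Every subcommand writes a JSON provenance log (input hashes, echoed
configuration) next to its artifacts.

## File formats

Station and CO2 records are plain CSV with ISO-8601 timestamps; ensemble
members travel as long-format CSV (`model_id, run_id, scenario, lat, lon,
humidity_kind, date, variable, value`); TRYs are CSV with a segment-id and
interpolation-flag column plus a JSON segment-plan sidecar; configs are
YAML.
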