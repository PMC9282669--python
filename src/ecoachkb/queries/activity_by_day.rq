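PREFIX onto: <https://example.org/ecoach/onto#>
SELECT ?participant ?datetime ?steps ?lpa ?mpa ?vpa ?sedentary ?sleep
WHERE {
  ?participant onto:hasHealthRecord ?record .
  ?record onto:hasBeenCollectedBy ?value .
  ?value onto:hasDateTime ?datetime .
  ?value onto:hasSteps ?steps .
  ?value onto:hasLpaMinutes ?lpa .
  ?value onto:hasMpaMinutes ?mpa .
  ?value onto:hasVpaMinutes ?vpa .
  ?value onto:hasSedentaryMinutes ?sedentary .
  ?value onto:hasSleepMinutes ?sleep .
}
ORDER BY ?participant ?datetime
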