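PREFIX onto: <https://example.org/ecoach/onto#>
SELECT ?participant ?goalType ?goalStyle ?responseType ?medium ?frequency
WHERE {
  ?participant onto:hasPreferences ?prefs .
  ?prefs onto:hasGoal ?goal .
  ?goal onto:hasGoalType ?goalType .
  ?goal onto:hasGoalStyle ?goalStyle .
  ?prefs onto:hasResponseType ?rt .
  ?rt onto:hasResponseTypeValue ?responseType .
  ?prefs onto:hasInteractionType ?it .
  ?it onto:hasInteractionMedium ?medium .
  ?it onto:hasInteractionFrequency ?frequency .
}
ORDER BY ?participant
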