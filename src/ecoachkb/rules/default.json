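{
  "comment": "Default rule base: 10 activity rules (R1-R8 assign the overall daily status for each goal-type x step x sleep combination; R9/R10 select ToDo and Informal messages through guarded slot decision tables), 1 satisfiability rule (R11, at most one once-a-day message per day) and 1 weather rule (R12).",
  "exclusivity_groups": {
    "once_a_day": ["A-13", "A-14"]
  },
  "rules": [
    {"id": "R1", "category": "activity",
     "if": "goal_generic and step_goal_met and sleep_goal_met",
     "then": [{"assign": "daily_goal_full", "value": true}]},
    {"id": "R2", "category": "activity",
     "if": "goal_generic and step_goal_met and not sleep_goal_met",
     "then": [{"assign": "daily_goal_partial", "value": true}]},
    {"id": "R3", "category": "activity",
     "if": "goal_generic and not step_goal_met and sleep_goal_met",
     "then": [{"assign": "daily_goal_partial", "value": true}]},
    {"id": "R4", "category": "activity",
     "if": "goal_generic and not step_goal_met and not sleep_goal_met",
     "then": [{"assign": "daily_goal_none", "value": true}]},
    {"id": "R5", "category": "activity",
     "if": "goal_personalized and step_goal_met and sleep_goal_met",
     "then": [{"assign": "daily_goal_full", "value": true}]},
    {"id": "R6", "category": "activity",
     "if": "goal_personalized and step_goal_met and not sleep_goal_met",
     "then": [{"assign": "daily_goal_partial", "value": true}]},
    {"id": "R7", "category": "activity",
     "if": "goal_personalized and not step_goal_met and sleep_goal_met",
     "then": [{"assign": "daily_goal_partial", "value": true}]},
    {"id": "R8", "category": "activity",
     "if": "goal_personalized and not step_goal_met and not sleep_goal_met",
     "then": [{"assign": "daily_goal_none", "value": true}]},
    {"id": "R9", "category": "activity",
     "if": "daily_goal_full or daily_goal_partial or daily_goal_none",
     "then": [{"emit_table": "todo_daily"}]},
    {"id": "R10", "category": "activity",
     "if": "daily_goal_full or daily_goal_partial or daily_goal_none",
     "then": [{"emit_table": "informal_daily"}]},
    {"id": "R11", "category": "satisfiability",
     "if": "true",
     "then": [{"assert_exclusive": "once_a_day"}]},
    {"id": "R12", "category": "weather",
     "if": "weather_outdoor_ok",
     "then": [{"emit": "C-1"}]}
  ],
  "decision_tables": {
    "todo_daily": [
      {"slot": "plan", "cases": [
        {"when": "goal_generic and step_goal_met and sleep_goal_met", "emit": "A-3"},
        {"when": "goal_generic and step_goal_met and not sleep_goal_met", "emit": "A-2"},
        {"when": "goal_generic and not step_goal_met", "emit": "A-1"},
        {"when": "goal_personalized and step_goal_met", "emit": "A-4"},
        {"when": "goal_personalized and not step_goal_met", "emit": "A-3"}]},
      {"slot": "coach", "cases": [
        {"when": "step_goal_met and sleep_goal_met", "emit": "A-6"},
        {"when": "not (step_goal_met and sleep_goal_met)", "emit": "A-5"}]},
      {"slot": "steps", "cases": [
        {"when": "step_goal_met", "emit": "A-8"},
        {"when": "not step_goal_met", "emit": "A-7"}]},
      {"slot": "target", "cases": [
        {"when": "goal_generic and step_goal_met", "emit": "A-10"},
        {"when": "goal_personalized and step_goal_met and sleep_goal_met", "emit": "A-10"},
        {"when": "goal_generic and not step_goal_met", "emit": "A-9"},
        {"when": "goal_personalized and not (step_goal_met and sleep_goal_met)", "emit": "A-9"}]},
      {"slot": "sleep", "cases": [
        {"when": "sleep_goal_met", "emit": "A-12"},
        {"when": "not sleep_goal_met", "emit": "A-11"}]}
    ],
    "informal_daily": [
      {"slot": "daily_summary", "cases": [
        {"when": "step_goal_met and sleep_goal_met", "emit": "A-13"},
        {"when": "not (step_goal_met and sleep_goal_met)", "emit": "A-14"}]}
    ]
  }
}
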