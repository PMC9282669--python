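{
  "comment": "Recommendation message registry. Codes and intents are the contract; text templates are synthetic placeholder reconstructions written in a positive-psychology / persuasion style and meant to be localized by users.",
  "messages": [
    {
      "code": "A-1",
      "intent": "ToDo",
      "components": {"time": "next_day", "element": "xsd:integer", "action": "popup", "subject": "steps"},
      "exclusivity_group": null,
      "text_template": "You need to complete {steps_remaining} more steps in the next {hours} hours to reach your daily goal."
    },
    {
      "code": "A-2",
      "intent": "ToDo",
      "components": {"time": "next_day", "element": "xsd:integer", "action": "popup", "subject": "steps"},
      "exclusivity_group": null,
      "text_template": "Nice progress on your steps. Plan a walk tomorrow and pair it with an earlier bedtime."
    },
    {
      "code": "A-3",
      "intent": "ToDo",
      "components": {"time": "next_day", "element": "xsd:integer", "action": "popup", "subject": "activity_plan"},
      "exclusivity_group": null,
      "text_template": "Keep your current routine going tomorrow: aim for {step_target} steps again."
    },
    {
      "code": "A-4",
      "intent": "ToDo",
      "components": {"time": "next_day", "element": "xsd:integer", "action": "popup", "subject": "activity_plan"},
      "exclusivity_group": null,
      "text_template": "Your personalized plan for tomorrow: repeat today's activity block and add {extra_minutes} active minutes."
    },
    {
      "code": "A-5",
      "intent": "ToDo",
      "components": {"time": "next_day", "element": "xsd:string", "action": "popup", "subject": "encouragement"},
      "exclusivity_group": null,
      "text_template": "A small push tomorrow gets you there - you are closer to your goal than you think."
    },
    {
      "code": "A-6",
      "intent": "ToDo",
      "components": {"time": "next_day", "element": "xsd:string", "action": "popup", "subject": "encouragement"},
      "exclusivity_group": null,
      "text_template": "Both daily goals reached - carry the momentum into tomorrow."
    },
    {
      "code": "A-7",
      "intent": "ToDo",
      "components": {"time": "next_day", "element": "xsd:integer", "action": "popup", "subject": "steps"},
      "exclusivity_group": null,
      "text_template": "Your step goal was out of reach today. Try splitting tomorrow's {step_target} steps into three shorter walks."
    },
    {
      "code": "A-8",
      "intent": "ToDo",
      "components": {"time": "next_day", "element": "xsd:integer", "action": "popup", "subject": "steps"},
      "exclusivity_group": null,
      "text_template": "Step goal met. Keep the same walking schedule tomorrow."
    },
    {
      "code": "A-9",
      "intent": "ToDo",
      "components": {"time": "next_day", "element": "xsd:integer", "action": "graph", "subject": "target"},
      "exclusivity_group": null,
      "text_template": "Check your progress chart and aim squarely at your target of {step_target} steps tomorrow."
    },
    {
      "code": "A-10",
      "intent": "ToDo",
      "components": {"time": "next_day", "element": "xsd:integer", "action": "graph", "subject": "target"},
      "exclusivity_group": null,
      "text_template": "Target on track - your progress chart is trending up. Hold the line tomorrow."
    },
    {
      "code": "A-11",
      "intent": "ToDo",
      "components": {"time": "next_day", "element": "xsd:integer", "action": "popup", "subject": "sleep"},
      "exclusivity_group": null,
      "text_template": "Sleep fell short of {sleep_target_min} minutes. Wind down {earlier_minutes} minutes earlier tonight."
    },
    {
      "code": "A-12",
      "intent": "ToDo",
      "components": {"time": "next_day", "element": "xsd:integer", "action": "popup", "subject": "sleep"},
      "exclusivity_group": null,
      "text_template": "Sleep goal met - keep the same bedtime tonight."
    },
    {
      "code": "A-13",
      "intent": "Informal",
      "components": {"time": "end_of_day", "element": "xsd:string", "action": "popup", "subject": "daily_summary"},
      "exclusivity_group": "once_a_day",
      "text_template": "Good work, keep it up! You have achieved the targeted steps."
    },
    {
      "code": "A-14",
      "intent": "Informal",
      "components": {"time": "end_of_day", "element": "xsd:string", "action": "popup", "subject": "daily_summary"},
      "exclusivity_group": "once_a_day",
      "text_template": "Not every day is perfect - tomorrow is a fresh start toward your goal."
    },
    {
      "code": "A-15",
      "intent": "Informal",
      "components": {"time": "end_of_week", "element": "xsd:string", "action": "popup", "subject": "weekly_summary"},
      "exclusivity_group": "once_a_week",
      "text_template": "Weekly goal achieved - a whole week of healthy activity. Congratulations!"
    },
    {
      "code": "A-16",
      "intent": "Informal",
      "components": {"time": "end_of_week", "element": "xsd:string", "action": "popup", "subject": "weekly_summary"},
      "exclusivity_group": "once_a_week",
      "text_template": "The weekly goal slipped away this time. Let's plan an achievable week ahead."
    },
    {
      "code": "C-1",
      "intent": "Informal",
      "components": {"time": "morning", "element": "xsd:string", "action": "popup", "subject": "weather"},
      "exclusivity_group": null,
      "text_template": "The weather looks good today - a fine day for outdoor activity in {city}."
    }
  ]
}
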