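# Example configuration for the `most` CLI and the library.
# Every key is optional; values shown are the defaults unless noted.
engine:
  monthly_interval_days: 30
  weekly_interval_days: 7
  reprompt_after_days: 1
  missing_after_days: 3
  missing_reschedule_days: 7
  escalation_window_days: 14
  escalation_rating: suboptimal   # "poor" for the strict variant
  horizon_days: 90
  video_url: "https://videos.example/library"
  web_checkin_url: "https://checkin.example/web"

# Optional template overrides/additions ({placeholder} grammar as in
# mostmh.messaging); skill texts are data, not code.
messages:
  - id: skill_gratitude_note
    kind: send_skill_message
    text: "Send a short thank-you message to someone who helped you this week."

# Rotation order for skill messages; ids must exist above or in the defaults.
skill_library:
  - skill_three_good_things
  - skill_gratitude_note
  - skill_thought_reframe
  - skill_opposite_action
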