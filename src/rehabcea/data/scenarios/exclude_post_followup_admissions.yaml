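# Exclude hospital admissions whose discharge fell after the follow-up period.
name: exclude_post_followup_admissions
exclusions: [post_followup_admissions]
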