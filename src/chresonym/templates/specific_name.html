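{% extends "base.html" %}
{% block title %}{{ entry.epithet }}{% endblock %}
{% block heading %}<em>{{ entry.epithet }}</em>{% endblock %}
{% block content %}
{% if entry.species_ids %}
<p>Refers to:
{% for sid in entry.species_ids %}
  <a href="{{ links.species(sid) }}"><em>{{ species_label(sid) }}</em></a>{{ "," if not loop.last }}
{% endfor %}
</p>
{% endif %}
{% if entry.original_spelling %}
<p>Original spelling: <em>{{ entry.original_spelling }}</em>
{% if entry.original_source %}
 in <a href="{{ links.publication(entry.original_source) }}">{{ entry.original_source }}</a>
{% if entry.original_year %} ({{ entry.original_year }}){% endif %}
{% endif %}
</p>
{% endif %}
{% if entry.etymology %}
<p>Etymology: {{ entry.etymology }}</p>
{% endif %}
{% if entry.variants %}
<p>Variant spellings: {% for v in entry.variants %}<em>{{ v }}</em>{{ ", " if not loop.last }}{% endfor %}</p>
{% endif %}
<h2>Names based on this specific name</h2>
<ul>
{% for name in entry.binomials %}
  <li><a href="{{ links.binomial(name) }}"><em>{{ name }}</em></a></li>
{% endfor %}
</ul>
{% for note in entry.notes %}
<p class="note">{{ note }}</p>
{% endfor %}
{% endblock %}
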